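# Methods

## Generative model of a mixed SILAC lane

A lane is described by a set of native species. Species *s* has a
composition (protein → copy number), a native mass *M_s* in kDa and a
per-condition abundance *A_s(c)* in arbitrary units. Its band center on
the slice axis follows the generating log-linear law

    mu_s = (log10(M_s) − a) / b,      a = 3.6,  b = −0.045  [log10(kDa)/slice]

with slice 1 at the top of the gel. These generating coefficients were
chosen once so that the full mass range of interest (~25–3,000 kDa) maps
inside a 64-slice lane with the largest supercomplexes a few slices from
the top; the calibration module must recover them from the standards, which
is the point of the consistency tests. The band shape is a unit-spacing
discretized Gaussian: slice *k* receives the probability mass of
N(mu_s, sigma²) on [k−½, k+½], with sigma = 1.0 slice, species-independent
(a single band-width knob; no band-broadening model is attempted).

Peptides are abstract reporters. Protein *p* has n_peptides = 4 by default,
each with a fixed positive response factor drawn from the cycle
(1.0, 0.6, 1.4, 0.8, 1.2); the expected intensity of peptide *j* of protein
*p* in slice *k* of the channel carrying condition *c* is

    E[I] = A_s(c) · copies_{p,s} · r_j · phi(k; mu_s, sigma)

summed over species containing *p*. Observed intensities are
E[I]·exp(eps), eps ~ N(0, sigma_ln²) with sigma_ln = 0.2 (typical
peptide-level MS variability), then censored to zero below the detection
limit 0.02, which reproduces the absent-peptide pattern of real data.
Noise is independent across slices, peptides, channels and experiments;
real inter-slice correlation is unknown and deliberately not modeled.
Channel contents follow the labeling design; a reciprocal pair consists of
two experiments with swapped heavy/light assignments and independent
noise. All draws come from one `numpy.random.default_rng(seed)` (PCG64)
generator, so a seed fixes the table byte-for-byte.

What the generator does *not* emulate: chromatography, isotope envelopes,
missed cleavages, ratio compression, inter-lane gel warping, and
peptide-level observability differences beyond the intensity response.
Passing recovery tests therefore shows the analysis chain is correct and
well-calibrated under multiplicative noise with censoring — not that it is
robust to every artifact of a real LC-MS complexome dataset.

### The default two-cell-line scenario

`default_scenario(detergent)` encodes a control line with an intact
respiratory chain against a mutant lacking the mitochondrially encoded
cytochrome b and hence holo-complex III. Species and abundances (a.u.):

| species | kDa (digitonin / DDM) | control | mutant | note |
|---|---|---|---|---|
| respirasome (cI+cIII₂+cIV) | 2,110 / — | 10 | 0 | digitonin only |
| holo complex I | 1,172 / 1,002 | 0 (dig) / 10 (DDM) | 0.61 | trace in mutant |
| pre-complex I (no N module) | 991 / 812 | 0 | 8 | carries NDUFAF2 |
| free N-module subunits | 30 | 0 | 2.5 | NDUFV1/NDUFV2 |
| holo complex III dimer | 500 / 485 | 6 | 0 | subunit copies = 2 |
| CYC1/UQCR10 intermediate | 150 | 0 | 3 | sequesters MT-CO2-module cIV subunits |
| complex II | 156 | 5 | 2.5 | partial assembly defect |
| complex V | 700 / 640 | 8 | 8 | unaffected |
| complex IV (core / MT-CO2 part) | 200 | 7 / 7 | 3 / 0 | MT-CO2 module sequestered in mutant |
| citrate-synthase dimer | 98 | 6 | 6 | internal standard |
| TOM complex | 440 | 5 | 5 | internal standard |

The mutant holo-cI abundance (0.61 vs the control respirasome's 10) plants
a 6.1 % windowed N-module fraction, the scale of residual maturation the
pipeline must resolve. The scenario emits matching standards (the complex
species themselves, at their generating positions, as is standard practice
for native gels) and a module annotation (cI N/Q/ND2/ND4/ND5, cIV
early/MT-CO2/MT-CO3, cV F1/peripheral stalk, restricted to subunits with
well-established module assignments). A second, higher-mass N-module
species sometimes reported near 1,386 kDa is omitted: under the generating
calibration it would sit 1.7 slices from the 1,172 kDa band,
irresolvable at sigma = 1 slice.

## Calibration

`fit_calibration` is ordinary least squares of log10(mass) on slice
position (≥ 3 standards; a non-negative slope is an "inverted gel" error).
The log-linear form is the standard Ferguson-style choice for
blue-native gels; no piecewise or errors-in-variables refinement is
attempted — standards are treated as trusted point estimates and slice
jitter only raises the reported residual SD. `mass_window_to_slices` maps
a ±tolerance (default 10 %) mass window to fractional slice bounds; a
window narrower than half a slice is widened to one full slice with a
warning so windowed integrals never degenerate (the 10 % default already
produces sub-slice windows at shallow calibration slopes, which is
accepted as-is).

## Profiles

Traces aggregate peptides by per-slice **sum** (less noisy); heatmaps use
the **most frequently observed peptide** per sample, ties broken by larger
total intensity then lexicographic peptide id. Channels are mapped to
conditions via the design before any comparison. The two conditions of one
experiment are normalized **jointly** by their common maximum — the
cross-condition scale comes entirely from the two channels of the same
mixed lane, so every intensity ratio is preserved and the larger condition
peaks at 1.0. Whether to normalize jointly or per condition with a
separate rescaling factor is genuinely open; joint normalization within
the mixed lane is the simpler, ratio-preserving choice made here. The
reciprocal pair is merged per slice as mean ± SEM (exact two-point formula
|x1−x2|/2 for n = 2 — descriptive, with no pretense of inferential power),
then the merged pair is rescaled once more so the joint maximum of the
mean traces is exactly 1. A per-protein summary log2(mutant/control) is
the median ratio over peptide-slice cells quantified in both channels;
proteins with no shared cell (typically present in only one line) get no
ratio and are reported per sample only. Module profiles are unweighted
means over member proteins' normalized traces, SEM across members;
unobserved members are skipped.

## Peaks and AUC

Peaks are local maxima of the 3-point moving-average-smoothed profile with
topographic prominence ≥ 0.1 × the smoothed maximum and centers ≥ 2 slices
apart (both configurable; the defaults suppress censoring-level bumps
while resolving bands ≥ 2 slices apart). Centers are refined by parabolic
interpolation through the three raw samples around the raw local maximum
(|shift| clamped to ½ slice); integration bounds are the flanking minima.
All integrals are trapezoidal on the integer slice axis with unit spacing
— profiles are never resampled to the mass axis. Windowed integrals take
fractional bounds with linear interpolation at the endpoints, making
window partitions exactly additive to the total. The windowed-fraction
statistic (e.g. how much N module reaches holo-complex size) is the
windowed AUC divided by the total AUC; the cross-condition ratio is 100 ×
windowed-AUC(A)/windowed-AUC(B) on jointly normalized profiles, undefined
(None) when the denominator is zero. Because both windows have equal width
on the slice axis (constant log-mass tolerance) and the band width is
species-independent, equal Gaussian spillover cancels from the ratio.

`compare_groups` delegates: per-subject two-sample t-tests (scipy) between
conditions with a Sidak family adjustment 1−(1−p)^m, plus a two-way
subject × condition ANOVA table (statsmodels) attached as metadata. Cells
with fewer than two replicates are excluded with a warning; two identical
groups return effect 0 and adjusted p = 1 rather than an undefined
zero-variance statistic.

## Co-IP enrichment

Protein-level ratios use summed channel intensities (the generative IP
model is protein-level); a peptide-median variant exists for peptide-level
tables. After orientation, experiment 1's ratio is plotted against
experiment 2's, so genuine effects fall on the diagonal. Classification
threshold is 1.0 log2 (a 2-fold change; the analysis reports magnitudes
and the cutoff is a package decision, exposed as a parameter):
sign-discordant pairs with both ratios beyond the threshold are
*inconsistent*; |mean| below the threshold is *unchanged*; otherwise
consistent evidence yields *depleted*/*enriched*. Single-experiment
proteins are classified from their one ratio and flagged by
`n_experiments = 1`.

## Numerical and testing notes

- Tables are tab-separated UTF-8 with '.' decimals and no quoting; writers
  emit six significant digits, fixed column order and key-sorted rows, so
  identical inputs give byte-identical files. Zero intensity and absent
  row are equivalent; writers omit zero rows.
- Band-shape normalization: the discretized Gaussian sums to 1 minus the
  tail mass outside the lane; the property test constrains centers to ≥ 5
  sigma from the lane edges, where the deficit is below 1e-6 (at exactly
  4 sigma a one-sided Gaussian tail is 3.2e-5, so a 1e-6 bound cannot hold
  there).
- Statistical test calibration: coverage-style checks use bands derived
  from the actual sampling distribution (e.g. a 2-SE band on 18 residual
  degrees of freedom has nominal coverage ≈ 0.94, asserted ≥ 0.88; the
  median of 30 shared cells with sigma = 0.2 noise on both channels has
  SE ≈ 0.093 log2 units, asserted within ≈ 2.7 SE in ≥ 95 % of
  replicates). All stochastic tests run with fixed seeds.
- Problem sizes: the recovery suites use the default scenario (~30
  proteins, 4 peptides each, 64 slices, two experiments) over 20–25 seeds
  and 100-replicate loops for the cheap scalar statistics; the whole suite
  runs in well under a minute on one CPU.

## Known limitations

- No de-novo complex discovery, profile clustering, or deconvolution of
  overlapping species; module membership is supplied a priori.
- No inter-lane alignment or gel-warping correction: comparisons are
  within mixed lanes by construction.
- The co-IP model has no background-binding structure (no CRAPome/SAINT
  analog); candidates are ranked by oriented ratio, not truth-labeled.
- Upstream spectral processing (search, protein inference, isotope
  quantification) is out of scope: the peptide slice table is the
  contract.
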