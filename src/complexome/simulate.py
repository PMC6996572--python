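"""Ground-truth simulation of two-condition, reciprocal-label SILAC complexome lanes.

The generator emulates the study design the downstream pipeline is built
for: two cell lines ("control" and "mutant") are mixed 1:1 in a single
blue-native lane, distinguishable because one carries heavy (K8/R10) and
the other light amino acids; the lane is cut into 64 one-millimetre slices
and every peptide is quantified per slice and channel.  The experiment is
performed twice with the labels swapped (a reciprocal pair).

A :class:`GroundTruthScenario` lists the native species present (holo-
complexes, supercomplexes, assembly intermediates, subcomplexes), each with
a composition (protein -> copy number), a native mass in kDa and a
per-condition abundance.  Migration position follows the generating
log-linear law log10(mass) = a + b*slice; the band of a species is a
discretized Gaussian of width ``peak_sigma_slices``.  Peptides are abstract
reporters with fixed positive response factors; observed intensities carry
multiplicative lognormal noise and are censored to zero below a detection
limit, reproducing the absent-peptide pattern of real data.  All draws come
from a single seeded :func:`numpy.random.default_rng` generator so that a
given seed always yields a byte-identical table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ClippedPeakWarning
from .tables import DEFAULT_N_SLICES, LabelingDesign

CONTROL = "control"
MUTANT = "mutant"

#: Generating calibration: log10(mass_kda) = GEN_A + GEN_B * slice.
GEN_A = 3.6
GEN_B = -0.045

#: Fixed cycle of per-peptide response factors (positive, mean ~1).
RESPONSE_CYCLE = (1.0, 0.6, 1.4, 0.8, 1.2)


@dataclass(frozen=True)
class SpeciesDefinition:
    """One native species: a complex, supercomplex, intermediate or subcomplex."""

    name: str
    composition: Mapping[str, int]
    mass_kda: float
    abundance: Mapping[str, float]
    detergent_scope: frozenset = frozenset({"DDM", "digitonin"})

    def __post_init__(self):
        if self.mass_kda <= 0:
            raise ValueError(f"species {self.name!r}: mass must be positive")
        if any(v < 0 for v in self.abundance.values()):
            raise ValueError(f"species {self.name!r}: abundances must be non-negative")


@dataclass(frozen=True)
class ProteinGenerativeModel:
    """Peptide-level heterogeneity of one protein: response factors per peptide."""

    protein_id: str
    n_peptides: int = 4
    peptide_response: tuple[float, ...] = ()
    observability: float = 1.0

    def __post_init__(self):
        if not self.peptide_response:
            object.__setattr__(
                self,
                "peptide_response",
                tuple(
                    RESPONSE_CYCLE[j % len(RESPONSE_CYCLE)] for j in range(self.n_peptides)
                ),
            )
        if any(r <= 0 for r in self.peptide_response):
            raise ValueError(f"{self.protein_id}: response factors must be positive")

    @property
    def peptide_ids(self) -> tuple[str, ...]:
        return tuple(f"{self.protein_id}_pep{j + 1}" for j in range(self.n_peptides))


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal intensity noise with detection-limit censoring."""

    sigma_ln: float = 0.2
    detection_limit: float = 0.02
    peak_sigma_slices: float = 1.0

    def __post_init__(self):
        if self.sigma_ln < 0 or self.detection_limit < 0 or self.peak_sigma_slices <= 0:
            raise ValueError("invalid noise parameters")


NOISELESS = NoiseModel(sigma_ln=0.0, detection_limit=0.0)


@dataclass(frozen=True)
class GroundTruthScenario:
    """Complete generative description of a pair of mixed lanes."""

    species: tuple[SpeciesDefinition, ...]
    proteins: Mapping[str, ProteinGenerativeModel]
    generating_calibration: tuple[float, float] = (GEN_A, GEN_B)
    conditions: tuple[str, str] = (CONTROL, MUTANT)
    n_slices: int = DEFAULT_N_SLICES

    def __post_init__(self):
        a, b = self.generating_calibration
        if b >= 0:
            raise ValueError("generating slope must be negative (mass decreases down the gel)")
        for sp in self.species:
            for pid in sp.composition:
                if pid not in self.proteins:
                    raise ValueError(f"species {sp.name!r}: no generative model for {pid!r}")

    @property
    def protein_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.proteins))

    def center_slice(self, mass_kda: float) -> float:
        a, b = self.generating_calibration
        return (np.log10(mass_kda) - a) / b

    def species_for(self, protein_id: str, condition: str | None = None):
        """Species containing a protein, optionally restricted to those present in a condition."""
        out = [sp for sp in self.species if protein_id in sp.composition]
        if condition is not None:
            out = [sp for sp in out if sp.abundance.get(condition, 0.0) > 0]
        return out

    def expected_profile(
        self, protein_id: str, condition: str, peak_sigma_slices: float = 1.0
    ) -> np.ndarray:
        """Noise-free expected per-slice intensity, summed over the protein's peptides."""
        model = self.proteins[protein_id]
        total_response = float(np.sum(model.peptide_response))
        out = np.zeros(self.n_slices)
        for sp in self.species:
            amount = sp.abundance.get(condition, 0.0) * sp.composition.get(protein_id, 0)
            if amount <= 0:
                continue
            mu = float(np.clip(self.center_slice(sp.mass_kda), 1, self.n_slices))
            out += amount * total_response * discretized_gaussian(
                mu, peak_sigma_slices, self.n_slices
            )
        return out


def discretized_gaussian(mu: float, sigma: float, n_slices: int) -> np.ndarray:
    """Per-slice band shape: the Gaussian mass within each unit slice bin.

    Slice k collects the probability mass of N(mu, sigma^2) on [k-1/2, k+1/2];
    the values sum to one up to the tail mass outside the lane.
    """
    k = np.arange(1, n_slices + 1, dtype=float)
    return norm.cdf(k + 0.5, mu, sigma) - norm.cdf(k - 0.5, mu, sigma)


def _expected_channel_profiles(
    scenario: GroundTruthScenario,
    condition: str,
    sigma_slices: float,
) -> dict[tuple[str, str], np.ndarray]:
    """Noise-free expected intensity per (protein, peptide) for one condition."""
    out: dict[tuple[str, str], np.ndarray] = {}
    for sp in scenario.species:
        abund = sp.abundance.get(condition, 0.0)
        if abund <= 0:
            continue
        mu_raw = scenario.center_slice(sp.mass_kda)
        mu = float(np.clip(mu_raw, 1, scenario.n_slices))
        if mu != mu_raw:
            warnings.warn(
                f"species {sp.name!r} migrates outside the lane (slice {mu_raw:.2f}); clipped",
                ClippedPeakWarning,
                stacklevel=3,
            )
        phi = discretized_gaussian(mu, sigma_slices, scenario.n_slices)
        for pid, copies in sp.composition.items():
            model = scenario.proteins[pid]
            for pep, resp in zip(model.peptide_ids, model.peptide_response):
                key = (pid, pep)
                contrib = abund * copies * resp * phi
                if key in out:
                    out[key] = out[key] + contrib
                else:
                    out[key] = contrib
    return out


def simulate_lane(
    scenario: GroundTruthScenario,
    design: LabelingDesign,
    experiment_id: str,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate one mixed lane (both channels of one experiment).

    The heavy channel carries the experiment's heavy-labeled condition and
    the light channel the other, per the labeling design.  Observed
    intensities are expected * exp(eps), eps ~ N(0, sigma_ln^2), censored to
    zero (row omitted) below the detection limit.  Deterministic given seed.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    records: list[tuple] = []
    for channel in ("H", "L"):
        condition = design.condition_of(experiment_id, channel)
        expected = _expected_channel_profiles(scenario, condition, noise.peak_sigma_slices)
        for (pid, pep) in sorted(expected):
            vec = expected[(pid, pep)]
            if noise.sigma_ln > 0:
                vec = vec * np.exp(rng.normal(0.0, noise.sigma_ln, scenario.n_slices))
            observed = np.where(vec >= noise.detection_limit, vec, 0.0) \
                if noise.detection_limit > 0 else vec
            for k in np.flatnonzero(observed > 0):
                records.append(
                    (experiment_id, channel, pid, pep, int(k) + 1, float(observed[k]))
                )
    return pd.DataFrame(
        records,
        columns=["experiment_id", "channel", "protein_id", "peptide_id", "slice", "intensity"],
    )


def simulate_reciprocal_pair(
    scenario: GroundTruthScenario,
    noise: NoiseModel | None = None,
    seeds: tuple[int, int] = (0, 1),
    experiment_ids: tuple[str, str] = ("exp1", "exp2"),
) -> tuple[pd.DataFrame, pd.DataFrame, LabelingDesign]:
    """Simulate the duplicate experiment with swapped labels.

    Experiment 1 labels the mutant condition heavy; experiment 2 swaps the
    assignment.  Noise is independent between the two experiments.
    """
    ctrl, mut = scenario.conditions
    design = LabelingDesign(
        {
            experiment_ids[0]: (mut, ctrl),
            experiment_ids[1]: (ctrl, mut),
        }
    )
    t1 = simulate_lane(scenario, design, experiment_ids[0], noise=noise, seed=seeds[0])
    t2 = simulate_lane(scenario, design, experiment_ids[1], noise=noise, seed=seeds[1])
    return t1, t2, design


# ---------------------------------------------------------------------------
# default two-cell-line scenario


@dataclass(frozen=True)
class ScenarioBundle:
    """A scenario together with its matching standards and module annotation."""

    scenario: GroundTruthScenario
    standards: pd.DataFrame
    modules: pd.DataFrame


#: Complex I structural subunits grouped by assembly module.
CI_MODULES: dict[str, tuple[str, ...]] = {
    "N": ("NDUFS1", "NDUFV1", "NDUFV2"),
    "Q": ("NDUFS2", "NDUFS3"),
    "ND2": ("NDUFA9",),
    "ND4": ("NDUFB11",),
    "ND5": ("NDUFB8",),
}
#: Complex IV subunits by assembly module (early / MT-CO2 / MT-CO3 stages).
CIV_MODULES: dict[str, tuple[str, ...]] = {
    "cIV_early": ("COX4I1", "COX5A", "HIGD1A"),
    "cIV_MT-CO2": ("MT-CO2", "COX5B", "COX6C"),
    "cIV_MT-CO3": ("COX6B1",),
}
#: ATP synthase modules: catalytic F1 particle and peripheral stalk.
CV_MODULES: dict[str, tuple[str, ...]] = {
    "cV_F1": ("ATP5A1", "ATP5B", "ATP5C1", "ATP5E"),
    "cV_peripheral_stalk": ("ATP5F1", "ATP5H", "ATP5O"),
}

CIII_CORE = ("UQCRC1", "UQCRC2", "UQCRFS1")
CI_NON_N = tuple(p for m, ps in CI_MODULES.items() if m != "N" for p in ps)
CI_ALL = tuple(p for ps in CI_MODULES.values() for p in ps)
CIV_ALL = tuple(p for ps in CIV_MODULES.values() for p in ps)
CV_ALL = tuple(p for ps in CV_MODULES.values() for p in ps)


def _species(name, members, mass, control, mutant, copies=None):
    comp = {p: (copies or {}).get(p, 1) for p in members}
    return SpeciesDefinition(
        name=name,
        composition=comp,
        mass_kda=mass,
        abundance={CONTROL: control, MUTANT: mutant},
    )


def default_scenario(detergent: str = "digitonin") -> ScenarioBundle:
    """The built-in control-vs-mutant fixture.

    The mutant condition models a cell line unable to make the mitochondrially
    encoded cytochrome b, hence without holo-complex III or any complex-III-
    containing supercomplex.  It accumulates the pre-complex-I intermediate
    (991 kDa in digitonin, 812 kDa in DDM) stabilized by NDUFAF2, retains only
    traces of holo complex I (1,172 kDa digitonin / 1,002 kDa DDM), piles up
    free N-module subunits at low mass, and sequesters MT-CO2-module complex
    IV subunits inside a stalled cytochrome-c1-containing subassembly.  The
    control condition carries the respirasome (2,110 kDa, digitonin only),
    holo complex III and fully assembled complex IV.  Citrate-synthase- and
    TOM-like proteins have identical abundance in both conditions and serve
    as internal standards.  Standards and module-annotation tables matching
    the scenario are returned alongside it.
    """
    if detergent not in ("digitonin", "DDM"):
        raise ValueError("detergent must be 'digitonin' or 'DDM'")
    dig = detergent == "digitonin"

    cIII_members = ("UQCRC1", "UQCRC2", "CYC1", "UQCRFS1", "UQCR10")
    cIII_copies = {p: 2 for p in cIII_members}  # the bc1 complex is dimeric
    resp_members = CI_ALL + cIII_members + ("COX4I1", "COX5A", "MT-CO2", "COX5B", "COX6C", "COX6B1")

    species: list[SpeciesDefinition] = []
    if dig:
        species.append(
            _species("respirasome", resp_members, 2110.0, 10.0, 0.0, copies=cIII_copies)
        )
        species.append(_species("holo_cI", CI_ALL, 1172.0, 0.0, 0.61))
        species.append(_species("pre_cI", CI_NON_N + ("NDUFAF2",), 991.0, 0.0, 8.0))
        species.append(
            _species("cIII2", cIII_members, 500.0, 6.0, 0.0, copies=cIII_copies)
        )
    else:
        species.append(_species("holo_cI", CI_ALL, 1002.0, 10.0, 0.61))
        species.append(_species("pre_cI", CI_NON_N + ("NDUFAF2",), 812.0, 0.0, 8.0))
        species.append(
            _species("cIII2", cIII_members, 485.0, 6.0, 0.0, copies=cIII_copies)
        )
    species.extend(
        [
            _species("N_module_free", ("NDUFV1", "NDUFV2"), 30.0, 0.0, 2.5),
            _species(
                "cyc1_intermediate",
                ("CYC1", "UQCR10", "MT-CO2", "COX5B", "COX6C"),
                150.0,
                0.0,
                3.0,
            ),
            _species("cII", ("SDHA", "SDHB"), 156.0, 5.0, 2.5),
            _species("cV", CV_ALL, 700.0 if dig else 640.0, 8.0, 8.0),
            _species(
                "cIV_core",
                ("COX4I1", "COX5A", "HIGD1A", "COX6B1", "NDUFA4"),
                200.0,
                7.0,
                3.0,
            ),
            _species("cIV_co2_assembled", ("MT-CO2", "COX5B", "COX6C"), 200.0, 7.0, 0.0),
            _species("CS_dimer", ("CS",), 98.0, 6.0, 6.0),
            _species("TOM_complex", ("TOMM20", "TOMM22"), 440.0, 5.0, 5.0),
        ]
    )

    protein_ids = sorted({p for sp in species for p in sp.composition})
    proteins = {pid: ProteinGenerativeModel(pid, n_peptides=4) for pid in protein_ids}
    scenario = GroundTruthScenario(species=tuple(species), proteins=proteins)

    # the complexes themselves serve as mass standards, at their generating positions
    std_names = [
        sp.name
        for sp in species
        if sp.name
        in (
            "respirasome",
            "holo_cI",
            "cV",
            "cIII2",
            "TOM_complex",
            "cIV_core",
            "cII",
            "CS_dimer",
            "N_module_free",
        )
    ]
    std_rows = []
    for sp in species:
        if sp.name in std_names:
            std_rows.append((sp.name, scenario.center_slice(sp.mass_kda), sp.mass_kda))
    standards = pd.DataFrame(std_rows, columns=["name", "slice_center", "mass_kda"])
    standards = standards.sort_values("slice_center", kind="stable").reset_index(drop=True)

    module_rows = []
    for modules in (CI_MODULES, CIV_MODULES, CV_MODULES):
        for mod, members in modules.items():
            for pid in members:
                module_rows.append((mod, pid))
    modules = pd.DataFrame(module_rows, columns=["module_name", "protein_id"])

    return ScenarioBundle(scenario=scenario, standards=standards, modules=modules)


def ratio_scenario(
    log2_ratios: Sequence[float] = (-3.0, -1.0, 0.0, 1.0),
    proteins_per_ratio: int = 3,
    base_abundance: float = 5.0,
) -> GroundTruthScenario:
    """Single-species proteins with planted mutant/control log2 abundance ratios.

    Used for ratio-recovery and orientation-consistency checks: protein
    ``rXX_pYY`` carries condition ratio 2**r with the species spread over
    distinct masses so bands do not overlap.
    """
    species = []
    proteins = {}
    masses = np.geomspace(60.0, 1800.0, len(log2_ratios) * proteins_per_ratio)
    i = 0
    for r in log2_ratios:
        for j in range(proteins_per_ratio):
            pid = f"r{r:+.0f}_p{j + 1}".replace("+", "p").replace("-", "m")
            proteins[pid] = ProteinGenerativeModel(pid, n_peptides=4)
            species.append(
                SpeciesDefinition(
                    name=f"sp_{pid}",
                    composition={pid: 1},
                    mass_kda=float(masses[i]),
                    abundance={CONTROL: base_abundance, MUTANT: base_abundance * 2.0**r},
                )
            )
            i += 1
    return GroundTruthScenario(species=tuple(species), proteins=proteins)


# ---------------------------------------------------------------------------
# co-immunopurification simulation


def simulate_ip(
    bait_complex: Sequence[str],
    n_background: int = 200,
    enrichment_log2: Mapping[str, float] | None = None,
    sigma: float = 0.3,
    seeds: tuple[int, int] = (0, 1),
    experiment_ids: tuple[str, str] = ("ip1", "ip2"),
    base_intensity: float = 100.0,
) -> tuple[pd.DataFrame, LabelingDesign]:
    """Simulate a reciprocal-label SILAC co-IP pair at the protein level.

    Every bait-complex and background protein receives, per experiment, an
    observed oriented log2(mutant/control) ratio equal to its planted effect
    plus N(0, sigma^2) noise, realized as channel intensities.  Background
    proteins have effect zero unless listed in ``enrichment_log2``.
    """
    enrichment_log2 = dict(enrichment_log2 or {})
    proteins = list(dict.fromkeys(list(bait_complex)))
    proteins += [f"bg{i + 1:04d}" for i in range(n_background)]
    effects = np.array([enrichment_log2.get(p, 0.0) for p in proteins], float)
    if not np.all(np.isfinite(effects)):
        raise ValueError("planted effects must be finite")

    design = LabelingDesign(
        {
            experiment_ids[0]: (MUTANT, CONTROL),
            experiment_ids[1]: (CONTROL, MUTANT),
        }
    )
    frames = []
    for exp, seed in zip(experiment_ids, seeds):
        rng = np.random.default_rng(seed)
        eps = rng.normal(0.0, sigma, len(proteins)) if sigma > 0 else np.zeros(len(proteins))
        mutant_channel = design.channel_of(exp, MUTANT)
        control_channel = design.channel_of(exp, CONTROL)
        mut_int = base_intensity * 2.0 ** (effects + eps)
        rows = []
        for p, mi in zip(proteins, mut_int):
            rows.append((exp, control_channel, p, base_intensity))
            rows.append((exp, mutant_channel, p, float(mi)))
        frames.append(
            pd.DataFrame(rows, columns=["experiment_id", "channel", "protein_id", "intensity"])
        )
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(
        ["experiment_id", "channel", "protein_id"], kind="stable"
    ).reset_index(drop=True)
    return table, design


def scenario_to_json(scenario: GroundTruthScenario) -> dict:
    """JSON-serializable ground-truth description for test harnesses."""
    return {
        "conditions": list(scenario.conditions),
        "n_slices": scenario.n_slices,
        "generating_calibration": {
            "a": scenario.generating_calibration[0],
            "b": scenario.generating_calibration[1],
        },
        "species": [
            {
                "name": sp.name,
                "mass_kda": sp.mass_kda,
                "composition": dict(sp.composition),
                "abundance": dict(sp.abundance),
            }
            for sp in scenario.species
        ],
        "proteins": {
            pid: {
                "n_peptides": m.n_peptides,
                "peptide_response": list(m.peptide_response),
            }
            for pid, m in scenario.proteins.items()
        },
    }
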