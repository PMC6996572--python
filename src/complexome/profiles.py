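"""From peptide slice tables to per-protein and per-module migration profiles.

The processing chain mirrors how comparative complexome figures are built:

1. aggregate each protein's peptides into a per-slice intensity vector for
   each channel of each experiment (sum over peptides for traces, or the
   most frequently observed peptide for heatmaps);
2. orient channels to biological conditions via the labeling design, so
   that downstream code never sees H/L;
3. normalize the two conditions of one experiment jointly, dividing both
   vectors by their common maximum so the relative inter-condition scale is
   preserved and the larger trace peaks at 1.0;
4. merge the reciprocal pair per condition as mean +- SEM (for n = 2 the
   SEM is exactly |x1 - x2| / 2);
5. optionally average member proteins into assembly-module profiles.

Cross-condition scale comes entirely from the two channels of the same
mixed lane; a per-protein summary log2(mutant/control) ratio is computed as
the median over peptide-slice cells quantified in both channels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import EmptyModuleError
from .tables import DEFAULT_N_SLICES, LabelingDesign


@dataclass
class MigrationProfile:
    """A per-subject intensity-versus-slice trace for one condition.

    ``values`` is the mean across experiments, ``sem`` its standard error
    (all zeros when only one experiment contributed), both of length
    n_slices.  ``observed`` is False when the subject never appeared in the
    underlying sample.
    """

    subject: str
    condition: str
    values: np.ndarray
    sem: np.ndarray
    n_experiments: int = 1
    observed: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.sem = np.asarray(self.sem, float)
        if self.values.shape != self.sem.shape:
            raise ValueError("values and sem must have equal length")


def build_protein_profile(
    table: pd.DataFrame,
    protein_id: str,
    experiment_id: str,
    channel: str,
    n_slices: int = DEFAULT_N_SLICES,
    method: str = "sum",
) -> tuple[np.ndarray, bool]:
    """Raw per-slice intensity vector of one protein in one sample.

    ``method='sum'`` adds all the protein's peptides per slice (the default
    for traces).  ``method='top_peptide'`` returns the single peptide
    observed (intensity > 0) in the most slices of that sample, the rule
    used for heatmap rows; ties go to the peptide with the larger total
    intensity, then to the lexicographically smaller peptide id.

    Returns ``(vector, observed)``; an absent protein yields a zero vector
    flagged unobserved.
    """
    if method not in ("sum", "top_peptide"):
        raise ValueError(f"unknown aggregation method {method!r}")
    sub = table[
        (table["experiment_id"] == experiment_id)
        & (table["channel"] == channel)
        & (table["protein_id"] == protein_id)
        & (table["intensity"] > 0)
    ]
    vec = np.zeros(n_slices)
    if sub.empty:
        return vec, False
    if method == "sum":
        agg = sub.groupby("slice")["intensity"].sum()
        vec[agg.index.to_numpy() - 1] = agg.to_numpy()
        return vec, True
    counts = sub.groupby("peptide_id").agg(
        n_slices_observed=("slice", "nunique"), total=("intensity", "sum")
    )
    counts = counts.sort_values(
        by=["n_slices_observed", "total", "peptide_id"],
        ascending=[False, False, True],
        kind="stable",
    )
    best = counts.index[0]
    pep = sub[sub["peptide_id"] == best]
    vec[pep["slice"].to_numpy() - 1] = pep["intensity"].to_numpy()
    return vec, True


def orient_experiment(
    table: pd.DataFrame,
    design: LabelingDesign,
    experiment_id: str,
    n_slices: int = DEFAULT_N_SLICES,
    method: str = "sum",
    proteins: list[str] | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-protein raw intensity vectors keyed by condition instead of channel."""
    if experiment_id not in design.experiments:
        raise KeyError(f"unknown experiment {experiment_id!r}")
    if proteins is None:
        proteins = sorted(
            table.loc[table["experiment_id"] == experiment_id, "protein_id"].unique()
        )
    out: dict[str, dict[str, np.ndarray]] = {}
    for pid in proteins:
        out[pid] = {}
        for channel in ("H", "L"):
            condition = design.condition_of(experiment_id, channel)
            vec, _ = build_protein_profile(
                table, pid, experiment_id, channel, n_slices=n_slices, method=method
            )
            out[pid][condition] = vec
    return out


def normalize_joint(
    control_vec: np.ndarray, mutant_vec: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Scale a condition pair by its single joint maximum.

    Both vectors are divided by the maximum over their concatenation, so
    every intra- and inter-condition ratio is unchanged and the larger
    condition peaks at exactly 1.  Returns ``(control, mutant,
    quantifiable)``; a pair that is identically zero is returned unchanged
    and flagged unquantifiable.
    """
    control_vec = np.asarray(control_vec, float)
    mutant_vec = np.asarray(mutant_vec, float)
    peak = max(control_vec.max(initial=0.0), mutant_vec.max(initial=0.0))
    if peak <= 0:
        return control_vec.copy(), mutant_vec.copy(), False
    return control_vec / peak, mutant_vec / peak, True


def shared_peptide_ratio(
    table: pd.DataFrame,
    design: LabelingDesign,
    protein_id: str,
    experiment_id: str,
    numerator_condition: str,
    denominator_condition: str,
) -> float | None:
    """Median log2 condition ratio over peptide-slice cells seen in both channels.

    For every (peptide, slice) cell of the protein quantified in both
    channels of the experiment, the oriented ratio numerator/denominator is
    formed; the summary is the log2 of the median ratio.  Returns None when
    no cell is shared (the protein is then reported per-sample only).
    """
    num_channel = design.channel_of(experiment_id, numerator_condition)
    den_channel = design.channel_of(experiment_id, denominator_condition)
    sub = table[
        (table["experiment_id"] == experiment_id)
        & (table["protein_id"] == protein_id)
        & (table["intensity"] > 0)
    ]
    if sub.empty:
        return None
    wide = sub.pivot_table(
        index=["peptide_id", "slice"], columns="channel", values="intensity", aggfunc="first"
    )
    if num_channel not in wide.columns or den_channel not in wide.columns:
        return None
    both = wide.dropna(subset=[num_channel, den_channel])
    if both.empty:
        return None
    ratios = both[num_channel].to_numpy() / both[den_channel].to_numpy()
    return float(np.log2(np.median(ratios)))


def merge_reciprocal(
    per_experiment: list[dict[str, np.ndarray]],
    subject: str,
) -> dict[str, MigrationProfile]:
    """Combine oriented, per-experiment-normalized vectors into mean +- SEM.

    With two experiments the per-slice SEM is exactly |x1 - x2| / 2 (the
    two-point formula); a single experiment passes through with zero SEM.
    No rescaling happens here.
    """
    if not per_experiment:
        raise ValueError("need at least one experiment")
    conditions = list(per_experiment[0])
    for other in per_experiment[1:]:
        if list(other) != conditions:
            raise ValueError("experiments disagree on conditions")
    out = {}
    for cond in conditions:
        vecs = [np.asarray(exp[cond], float) for exp in per_experiment]
        if len({v.size for v in vecs}) > 1:
            raise ValueError("mismatched profile lengths")
        stack = np.vstack(vecs)
        mean = stack.mean(axis=0)
        if stack.shape[0] == 1:
            sem = np.zeros_like(mean)
        elif stack.shape[0] == 2:
            sem = np.abs(stack[0] - stack[1]) / 2.0
        else:
            sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
        out[cond] = MigrationProfile(
            subject=subject,
            condition=cond,
            values=mean,
            sem=sem,
            n_experiments=stack.shape[0],
            observed=bool(stack.any()),
        )
    return out


def _joint_rescale(profiles: dict[str, MigrationProfile]) -> dict[str, MigrationProfile]:
    """Rescale a condition pair of merged profiles so the joint max mean is 1."""
    peak = max(p.values.max(initial=0.0) for p in profiles.values())
    if peak <= 0:
        return profiles
    return {
        cond: replace(p, values=p.values / peak, sem=p.sem / peak)
        for cond, p in profiles.items()
    }


def build_condition_profiles(
    tables: list[pd.DataFrame],
    design: LabelingDesign,
    n_slices: int = DEFAULT_N_SLICES,
    method: str = "sum",
    proteins: list[str] | None = None,
) -> dict[str, dict[str, MigrationProfile]]:
    """Full chain: orient, normalize per experiment, merge, joint-rescale.

    ``tables`` holds one peptide table per experiment of the design (a
    single concatenated table is also accepted).  Returns
    ``{protein: {condition: MigrationProfile}}`` with, per protein, the
    maximum over both conditions' mean traces equal to 1 unless the protein
    was never observed.
    """
    table = pd.concat(tables, ignore_index=True) if len(tables) > 1 else tables[0]
    if proteins is None:
        proteins = sorted(table["protein_id"].unique())
    ctrl, mut = sorted(design.conditions)
    oriented = {
        exp: orient_experiment(
            table, design, exp, n_slices=n_slices, method=method, proteins=proteins
        )
        for exp in design.experiment_ids
        if (table["experiment_id"] == exp).any()
    }
    out: dict[str, dict[str, MigrationProfile]] = {}
    for pid in proteins:
        per_exp = []
        for exp in oriented:
            c, m, quantifiable = normalize_joint(
                oriented[exp][pid][ctrl], oriented[exp][pid][mut]
            )
            per_exp.append({ctrl: c, mut: m})
        merged = merge_reciprocal(per_exp, subject=pid)
        out[pid] = _joint_rescale(merged)
    return out


def module_profile(
    protein_profiles: dict[str, dict[str, MigrationProfile]],
    annotation: pd.DataFrame,
    module_name: str,
) -> dict[str, MigrationProfile]:
    """Average the normalized traces of a module's member proteins.

    Per condition, the module trace is the unweighted per-slice mean over
    members with an observed profile; SEM is taken across members.  Members
    absent from the data are skipped; a module with no observed member is
    an error.
    """
    members = annotation.loc[
        annotation["module_name"] == module_name, "protein_id"
    ].tolist()
    present = [
        p
        for p in members
        if p in protein_profiles
        and any(prof.observed for prof in protein_profiles[p].values())
    ]
    if not present:
        raise EmptyModuleError(f"no member of module {module_name!r} was observed")
    conditions = list(protein_profiles[present[0]])
    out = {}
    for cond in conditions:
        stack = np.vstack([protein_profiles[p][cond].values for p in present])
        mean = stack.mean(axis=0)
        if stack.shape[0] > 1:
            sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
        else:
            sem = np.zeros_like(mean)
        n_exp = max(protein_profiles[p][cond].n_experiments for p in present)
        out[cond] = MigrationProfile(
            subject=module_name,
            condition=cond,
            values=mean,
            sem=sem,
            n_experiments=n_exp,
            observed=bool(stack.any()),
        )
    return out


def heatmap_matrix(
    table: pd.DataFrame,
    subjects: list[str],
    experiment_id: str,
    channel: str,
    n_slices: int = DEFAULT_N_SLICES,
) -> pd.DataFrame:
    """Per-sample heatmap rows: most-frequent-peptide vector scaled to row max 1.

    One row per subject, columns are slices 1..n_slices, cells in [0, 1]
    (0 = absent, 0.5 = half-maximal, 1 = the row's own maximum).  All-zero
    rows of unobserved subjects are retained.
    """
    rows = {}
    for pid in subjects:
        vec, _ = build_protein_profile(
            table, pid, experiment_id, channel, n_slices=n_slices, method="top_peptide"
        )
        peak = vec.max(initial=0.0)
        rows[pid] = vec / peak if peak > 0 else vec
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=range(1, n_slices + 1)
    )
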