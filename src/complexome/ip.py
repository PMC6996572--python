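"""Scoring of reciprocal-label SILAC co-immunopurification experiments.

A bait protein is immunopurified from the two mixed, differentially labeled
cell lines; each co-purified protein yields one heavy/light intensity ratio
per experiment.  After orienting both experiments' ratios to the same
mutant-over-control direction via the labeling design, a protein with a
real abundance difference falls on the diagonal of the (experiment 1,
experiment 2) log2-ratio scatter.  Proteins are then classified as
depleted, enriched, unchanged or inconsistent with a symmetric log2
threshold.

Protein-level ratios are computed from summed channel intensities per
protein (the generative model here is protein-level); a peptide-median
variant is available for tables carrying a ``peptide_id`` column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import LabelingDesign

CLASS_DEPLETED = "depleted"
CLASS_ENRICHED = "enriched"
CLASS_UNCHANGED = "unchanged"
CLASS_INCONSISTENT = "inconsistent"


def oriented_ip_ratios(
    table: pd.DataFrame,
    design: LabelingDesign,
    numerator_condition: str,
    denominator_condition: str,
    method: str = "sum",
) -> pd.DataFrame:
    """Per-protein oriented log2 ratios for each experiment of an IP pair.

    ``table`` is long-form with columns {experiment_id, protein_id, channel,
    intensity} (optionally peptide_id when ``method='peptide_median'``).
    The returned frame has one row per protein with ``x_log2`` (first
    experiment), ``y_log2`` (second experiment), ``mean_log2`` over the
    available experiments and ``n_experiments``.  A protein missing one
    channel of an experiment has no ratio there (NaN) and is carried with
    ``n_experiments`` reduced, mirroring single-experiment plotting.
    """
    if method not in ("sum", "peptide_median"):
        raise ValueError(f"unknown method {method!r}")
    exp_ids = design.experiment_ids
    if len(exp_ids) != 2:
        raise ValueError("IP scoring expects a reciprocal pair of experiments")

    per_exp: dict[str, pd.Series] = {}
    for exp in exp_ids:
        num_ch = design.channel_of(exp, numerator_condition)
        den_ch = design.channel_of(exp, denominator_condition)
        sub = table[(table["experiment_id"] == exp) & (table["intensity"] > 0)]
        if method == "sum":
            agg = sub.groupby(["protein_id", "channel"])["intensity"].sum().unstack()
            if num_ch in agg.columns and den_ch in agg.columns:
                per_exp[exp] = np.log2(agg[num_ch] / agg[den_ch])
            else:
                per_exp[exp] = pd.Series(dtype=float)
        else:
            wide = sub.pivot_table(
                index=["protein_id", "peptide_id"],
                columns="channel",
                values="intensity",
                aggfunc="sum",
            )
            if num_ch in wide.columns and den_ch in wide.columns:
                both = wide.dropna(subset=[num_ch, den_ch])
                per_exp[exp] = np.log2(
                    (both[num_ch] / both[den_ch]).groupby("protein_id").median()
                )
            else:
                per_exp[exp] = pd.Series(dtype=float)

    out = pd.DataFrame(
        {
            "x_log2": per_exp[exp_ids[0]],
            "y_log2": per_exp[exp_ids[1]],
        }
    )
    out.index.name = "protein_id"
    out = out.reset_index()
    out["mean_log2"] = out[["x_log2", "y_log2"]].mean(axis=1, skipna=True)
    out["n_experiments"] = out[["x_log2", "y_log2"]].notna().sum(axis=1).astype(int)
    return out.sort_values("protein_id", kind="stable").reset_index(drop=True)


def classify_interactors(
    points: pd.DataFrame, changed_threshold_log2: float = 1.0
) -> pd.DataFrame:
    """Attach a consistency flag and an interactor class to oriented points.

    Rules, in order of precedence: both experiments beyond the threshold
    with discordant signs -> inconsistent; |mean| below the threshold ->
    unchanged; mean at or beyond the threshold with concordant (or single-
    experiment) evidence -> depleted / enriched.  ``consistent`` is True
    when the two oriented ratios share a sign or both sit inside the
    unchanged band.
    """
    thr = float(changed_threshold_log2)
    out = points.copy()
    x = out["x_log2"].to_numpy(float)
    y = out["y_log2"].to_numpy(float)
    mean = out["mean_log2"].to_numpy(float)
    n = out["n_experiments"].to_numpy(int)

    both = n == 2
    same_sign = np.sign(x) == np.sign(y)
    in_band = (np.abs(x) < thr) & (np.abs(y) < thr)
    consistent = np.where(both, same_sign | in_band, True)

    discordant = both & ~same_sign & (np.abs(x) >= thr) & (np.abs(y) >= thr)
    classes = np.full(len(out), CLASS_UNCHANGED, dtype=object)
    classes[discordant] = CLASS_INCONSISTENT
    changed = ~discordant & (np.abs(mean) >= thr) & consistent
    classes[changed & (mean <= -thr)] = CLASS_DEPLETED
    classes[changed & (mean >= thr)] = CLASS_ENRICHED
    inconsistent_mean = ~discordant & (np.abs(mean) >= thr) & ~consistent
    classes[inconsistent_mean] = CLASS_INCONSISTENT
    classes[n == 0] = CLASS_UNCHANGED

    out["consistent"] = consistent.astype(bool)
    out["interactor_class"] = classes
    return out


def enrichment_scatter(
    points: pd.DataFrame, path: str | None = None
) -> "pd.DataFrame | tuple":
    """Scatter of experiment-1 versus experiment-2 oriented log2 ratios.

    True effects fall on the diagonal because both axes are oriented the
    same way (the second experiment's raw heavy/light axis is reversed by
    the orientation step).  Proteins quantified in only one experiment are
    drawn on the corresponding axis.  The classified table is always
    returned; when ``path`` is given a PNG/SVG is also written.
    """
    out = points.copy()
    if path is None:
        return out
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        CLASS_DEPLETED: "tab:blue",
        CLASS_ENRICHED: "tab:red",
        CLASS_UNCHANGED: "0.6",
        CLASS_INCONSISTENT: "tab:orange",
    }
    fig, ax = plt.subplots(figsize=(5, 5))
    for cls, sub in out.groupby("interactor_class"):
        x = sub["x_log2"].fillna(0.0)
        y = sub["y_log2"].fillna(0.0)
        ax.scatter(x, y, s=12, label=cls, color=colors.get(cls, "k"), alpha=0.7)
    lim = np.nanmax(np.abs(out[["x_log2", "y_log2"]].to_numpy(float))) if len(out) else 1.0
    lim = max(float(lim) * 1.1, 1.0)
    ax.plot([-lim, lim], [-lim, lim], ls="--", lw=0.8, color="k")
    ax.axhline(0, lw=0.5, color="k")
    ax.axvline(0, lw=0.5, color="k")
    ax.set_xlabel("experiment 1 log2(mutant/control)")
    ax.set_ylabel("experiment 2 log2(mutant/control)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return out, path
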