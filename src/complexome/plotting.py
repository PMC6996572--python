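"""Optional rendering of profiles and heatmaps (all analysis is plot-free)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap

from .calibration import CalibrationCurve

#: Black -> yellow -> red, anchored at 0 / 0.5 / 1 relative intensity.
HEAT_CMAP = LinearSegmentedColormap.from_list(
    "bn_heat", [(0.0, "black"), (0.5, "yellow"), (1.0, "red")]
)


def render_heatmap(matrix: pd.DataFrame, path: str) -> str:
    """Render a per-sample heatmap matrix (rows = subjects, columns = slices)."""
    fig, ax = plt.subplots(
        figsize=(8, max(1.5, 0.25 * len(matrix)))
    )
    ax.imshow(
        matrix.to_numpy(float), aspect="auto", cmap=HEAT_CMAP, vmin=0.0, vmax=1.0,
        interpolation="nearest",
    )
    ax.set_yticks(range(len(matrix)))
    ax.set_yticklabels(matrix.index, fontsize=6)
    ax.set_xlabel("slice")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_profile_pair(
    profiles: dict, path: str, curve: CalibrationCurve | None = None
) -> str:
    """Plot a condition pair of migration profiles as mean +- SEM traces.

    Control-like condition in blue, the other in red, following the usual
    coloring of comparative complexome figures; if a calibration curve is
    given the top axis shows apparent native mass.
    """
    fig, ax = plt.subplots(figsize=(6, 3))
    colors = {}
    for i, cond in enumerate(sorted(profiles)):
        colors[cond] = ["tab:blue", "tab:red"][i % 2]
    subject = ""
    for cond, prof in sorted(profiles.items()):
        x = np.arange(1, prof.values.size + 1)
        ax.plot(x, prof.values, color=colors[cond], label=cond, lw=1.2)
        ax.fill_between(
            x, prof.values - prof.sem, prof.values + prof.sem,
            color=colors[cond], alpha=0.25, lw=0,
        )
        subject = prof.subject
    ax.set_xlabel("slice")
    ax.set_ylabel("relative intensity")
    ax.set_title(subject)
    ax.legend(frameon=False, fontsize=8)
    if curve is not None:
        top = ax.secondary_xaxis(
            "top", functions=(lambda s: curve.mass_at(s), lambda m: curve.slice_at(np.maximum(m, 1e-9)))
        )
        top.set_xlabel("apparent mass (kDa)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
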