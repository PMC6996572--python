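"""Peak detection, AUC quantification and cross-condition comparison.

All integrals use the trapezoid rule directly on the integer slice axis
(unit spacing, slices 1..n); profiles are never resampled to the mass axis
first.  Windowed integrals take fractional slice bounds with linear
interpolation at the endpoints, which makes window partitions exactly
additive.  Group comparisons delegate to standard two-factor analysis with
a Sidak-family correction rather than re-deriving any statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks

from .calibration import CalibrationCurve, mass_window_to_slices


@dataclass(frozen=True)
class Peak:
    """One detected migration peak with its integration bounds."""

    subject: str
    condition: str
    center_slice: float
    apparent_mass_kda: float
    left_slice: int
    right_slice: int
    auc: float
    prominence: float


def total_auc(values: np.ndarray) -> float:
    """Trapezoidal integral of a profile over the whole slice axis."""
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValueError("profile must have at least two slices")
    return float(np.trapezoid(values))


def trapezoid_between(values: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral between fractional slice positions.

    Profile values are interpreted as samples at slice coordinates 1..n and
    linearly interpolated at the fractional bounds, so integrals over a
    partition of [1, n] sum exactly to the total.
    """
    values = np.asarray(values, float)
    n = values.size
    lo = float(np.clip(lo, 1, n))
    hi = float(np.clip(hi, 1, n))
    if hi <= lo:
        return 0.0
    xs = np.concatenate(
        ([lo], np.arange(np.floor(lo) + 1, np.ceil(hi)), [hi])
    )
    xs = xs[(xs >= lo) & (xs <= hi)]
    ys = np.interp(xs, np.arange(1, n + 1), values)
    return float(np.trapezoid(ys, xs))


def _smooth3(values: np.ndarray) -> np.ndarray:
    """3-point moving average with edge replication."""
    padded = np.concatenate(([values[0]], values, [values[-1]]))
    return np.convolve(padded, np.ones(3) / 3.0, mode="valid")


def detect_peaks(
    values: np.ndarray,
    min_prominence: float = 0.1,
    min_separation: int = 2,
    curve: CalibrationCurve | None = None,
    subject: str = "",
    condition: str = "",
) -> list[Peak]:
    """Locate migration peaks in a (typically normalized) profile.

    Candidate peaks are local maxima of the 3-point moving-average-smoothed
    profile with topographic prominence of at least ``min_prominence`` times
    the smoothed maximum, and at least ``min_separation`` slices apart.  The
    reported center is refined by parabolic interpolation through the three
    raw samples around the raw local maximum; integration bounds are the
    flanking minima (peak bases), and the peak AUC integrates the raw
    profile between them.  An all-zero or flat profile yields no peaks.
    """
    values = np.asarray(values, float)
    if values.size < 3 or not np.any(values > 0):
        return []
    smoothed = _smooth3(values)
    top = smoothed.max()
    if top <= 0:
        return []
    idx, props = find_peaks(
        smoothed, distance=max(int(min_separation), 1), prominence=min_prominence * top
    )
    peaks = []
    n = values.size
    for i, prom in zip(idx, props["prominences"]):
        # re-center on the raw profile near the smoothed maximum
        lo = max(i - 1, 0)
        j = lo + int(np.argmax(values[lo : min(i + 2, n)]))
        if 0 < j < n - 1:
            yl, yc, yr = values[j - 1], values[j], values[j + 1]
            denom = yl - 2 * yc + yr
            delta = 0.5 * (yl - yr) / denom if denom < 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        center = (j + 1) + delta
        left = int(props["left_bases"][list(idx).index(i)]) + 1
        right = int(props["right_bases"][list(idx).index(i)]) + 1
        auc = trapezoid_between(values, left, right)
        peaks.append(
            Peak(
                subject=subject,
                condition=condition,
                center_slice=float(center),
                apparent_mass_kda=float(curve.mass_at(center)) if curve else float("nan"),
                left_slice=left,
                right_slice=right,
                auc=auc,
                prominence=float(prom / top),
            )
        )
    return sorted(peaks, key=lambda p: p.center_slice)


def windowed_auc(
    values: np.ndarray,
    curve: CalibrationCurve,
    center_kda: float,
    tolerance_fraction: float = 0.10,
) -> dict:
    """Trapezoidal integral restricted to a +-tolerance native-mass window.

    Returns the windowed AUC, its fraction of the profile's total AUC, and
    the fractional slice bounds used.
    """
    values = np.asarray(values, float)
    lo, hi = mass_window_to_slices(
        curve, center_kda, tolerance_fraction, n_slices=values.size
    )
    auc = trapezoid_between(values, lo, hi)
    total = total_auc(values)
    return {
        "auc": auc,
        "fraction_of_total": auc / total if total > 0 else 0.0,
        "window": (lo, hi),
    }


def cross_condition_peak_ratio(
    values_a: np.ndarray,
    window_a_kda: float,
    values_b: np.ndarray,
    window_b_kda: float,
    curve: CalibrationCurve,
    tolerance_fraction: float = 0.10,
) -> float | None:
    """Windowed AUC of profile A as a percentage of windowed AUC of profile B.

    Both profiles must be on the same (jointly normalized) scale.  Returns
    None when the denominator window integrates to zero.
    """
    num = windowed_auc(values_a, curve, window_a_kda, tolerance_fraction)["auc"]
    den = windowed_auc(values_b, curve, window_b_kda, tolerance_fraction)["auc"]
    if den <= 0:
        return None
    return 100.0 * num / den


def compare_groups(auc_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Two-factor (subject x condition) comparison of replicate AUCs.

    ``auc_table`` is long-form with columns {subject, condition, auc} and at
    least two replicate rows per (subject, condition) cell; cells with fewer
    replicates are excluded with a warning.  Per subject, the two conditions
    are compared by a t-test with a Sidak multiplicity adjustment across
    subjects; the overall two-way ANOVA table (statsmodels) is attached as
    ``result.attrs['anova']``.  This is a thin contract over standard
    routines, not a re-derivation.
    """
    required = {"subject", "condition", "auc"}
    if not required.issubset(auc_table.columns):
        raise ValueError(f"auc_table needs columns {sorted(required)}")
    conditions = sorted(auc_table["condition"].unique())
    if len(conditions) != 2:
        raise ValueError("compare_groups expects exactly two conditions")
    c1, c2 = conditions

    counts = auc_table.groupby(["subject", "condition"]).size().unstack(fill_value=0)
    ok = counts[(counts >= 2).all(axis=1)].index.tolist()
    dropped = sorted(set(auc_table["subject"]) - set(ok))
    if dropped:
        warnings.warn(
            f"excluding subjects with <2 replicates per cell: {dropped}", UserWarning,
            stacklevel=2,
        )
    data = auc_table[auc_table["subject"].isin(ok)]

    rows = []
    m = len(ok)
    for subject in sorted(ok):
        g1 = data.loc[
            (data["subject"] == subject) & (data["condition"] == c1), "auc"
        ].to_numpy(float)
        g2 = data.loc[
            (data["subject"] == subject) & (data["condition"] == c2), "auc"
        ].to_numpy(float)
        effect = float(g2.mean() - g1.mean())
        if g1.var(ddof=1) == 0 and g2.var(ddof=1) == 0:
            p = 1.0 if effect == 0 else 0.0
            t = 0.0 if effect == 0 else float("inf")
        else:
            t, p = stats.ttest_ind(g2, g1, equal_var=True)
        p_adj = float(1.0 - (1.0 - min(p, 1.0)) ** m)
        rows.append(
            {
                "subject": subject,
                f"mean_{c1}": float(g1.mean()),
                f"mean_{c2}": float(g2.mean()),
                "effect": effect,
                "t": float(t),
                "p_raw": float(p),
                "p_adj": p_adj,
                "significant": bool(p_adj < alpha),
            }
        )
    result = pd.DataFrame(rows)

    try:
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        model = smf.ols("auc ~ C(subject) * C(condition)", data=data).fit()
        result.attrs["anova"] = anova_lm(model, typ=2)
    except (ValueError, np.linalg.LinAlgError):  # degenerate designs
        result.attrs["anova"] = None
    return result
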