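"""Native-mass calibration of a blue-native gel lane.

Intact complexes of known native mass ("standards") migrate to reproducible
slice positions; their positions define a Ferguson-style log-linear law

    log10(mass_kda) = a + b * slice,        b < 0,

with slice 1 at the top of the gel (largest species).  The curve is fitted
by ordinary least squares of log10(mass) on slice position and then inverted
to convert detected peak centers into apparent native masses in kDa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateWindowWarning, InvertedGelOrientationError, UnderdeterminedError
from .tables import DEFAULT_N_SLICES


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted slice <-> log10(native mass) mapping.

    intercept_a and slope_b are in log10(kDa) and log10(kDa)/slice;
    residual_sd is the root-mean-square residual of the fit in log10(kDa).
    """

    intercept_a: float
    slope_b: float
    residual_sd: float
    n_standards: int

    def mass_at(self, slice_pos: float | np.ndarray) -> float | np.ndarray:
        """Apparent native mass (kDa) at a (possibly fractional) slice position."""
        return 10.0 ** (self.intercept_a + self.slope_b * np.asarray(slice_pos, float))

    def slice_at(self, mass_kda: float | np.ndarray) -> float | np.ndarray:
        """Slice position at which a species of the given mass migrates."""
        mass = np.asarray(mass_kda, float)
        if np.any(mass <= 0):
            raise ValueError("mass query must be positive")
        return (np.log10(mass) - self.intercept_a) / self.slope_b


def fit_calibration(standards: pd.DataFrame) -> CalibrationCurve:
    """Least-squares fit of log10(mass_kda) on slice_center.

    Requires at least three standards; a non-negative fitted slope means the
    gel orientation is inverted (mass must decrease down the lane) and is an
    error rather than a warning.
    """
    if len(standards) < 3:
        raise UnderdeterminedError(
            f"need at least 3 standards, got {len(standards)}"
        )
    x = standards["slice_center"].to_numpy(float)
    y = np.log10(standards["mass_kda"].to_numpy(float))
    b, a = np.polyfit(x, y, 1)
    if b >= 0:
        raise InvertedGelOrientationError(
            f"fitted slope {b:.4g} >= 0: standards imply mass increasing down the gel"
        )
    resid = y - (a + b * x)
    dof = max(len(x) - 2, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    return CalibrationCurve(
        intercept_a=float(a),
        slope_b=float(b),
        residual_sd=residual_sd,
        n_standards=len(x),
    )


def mass_at(curve: CalibrationCurve, slice_pos: float) -> float:
    return float(curve.mass_at(slice_pos))


def slice_at(curve: CalibrationCurve, mass_kda: float) -> float:
    return float(curve.slice_at(mass_kda))


def mass_window_to_slices(
    curve: CalibrationCurve,
    center_kda: float,
    tolerance_fraction: float = 0.10,
    n_slices: int = DEFAULT_N_SLICES,
) -> tuple[float, float]:
    """Slice interval covering masses within +-tolerance_fraction of a center mass.

    Returns fractional (slice_lo, slice_hi) clipped to [1, n_slices].  The
    higher-mass edge of the window maps to the smaller slice index.  A window
    narrower than half a slice is widened to one full slice with a warning so
    that a windowed integral never degenerates to a point.
    """
    if not 0 <= tolerance_fraction < 1:
        raise ValueError("tolerance_fraction must be in [0, 1)")
    lo = slice_at(curve, center_kda * (1 + tolerance_fraction))
    hi = slice_at(curve, center_kda * (1 - tolerance_fraction)) if tolerance_fraction > 0 else lo
    lo, hi = min(lo, hi), max(lo, hi)
    if hi - lo < 0.5:
        mid = 0.5 * (lo + hi)
        lo, hi = mid - 0.5, mid + 0.5
        warnings.warn(
            f"mass window around {center_kda:g} kDa narrower than one slice; widened",
            DegenerateWindowWarning,
            stacklevel=2,
        )
    lo = float(np.clip(lo, 1, n_slices))
    hi = float(np.clip(hi, 1, n_slices))
    return lo, hi
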