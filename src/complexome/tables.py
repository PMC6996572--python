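"""Readers and writers for every on-disk artifact of the pipeline.

All tabular artifacts are tab-separated UTF-8 text with a ``.`` decimal
separator and no quoting; the labeling design and calibration curve travel
as JSON.  Writers are deterministic: fixed column order, floats rendered
with six significant digits, rows sorted by their declared keys, so that
identical inputs always produce byte-identical files.

The peptide slice table is the pipeline's sole quantitative input: one row
per (experiment, channel, protein, peptide, slice) with a non-negative
intensity in arbitrary units.  A zero intensity and an absent row mean the
same thing ("not observed"); writers therefore omit zero rows and no reader
ever imputes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateKeyError,
    NonMonotoneStandardsWarning,
    NotReciprocalWarning,
    TableValidationError,
    UnderdeterminedError,
)

PEPTIDE_COLUMNS = (
    "experiment_id",
    "channel",
    "protein_id",
    "peptide_id",
    "slice",
    "intensity",
)
PEPTIDE_KEY = PEPTIDE_COLUMNS[:5]
STANDARDS_COLUMNS = ("name", "slice_center", "mass_kda")
MODULES_COLUMNS = ("module_name", "protein_id")
CHANNELS = ("H", "L")

DEFAULT_N_SLICES = 64


def _fmt(x: float) -> str:
    """Render a float with six significant digits, locale-independent."""
    return format(float(x), ".6g")


@dataclass(frozen=True)
class LabelingDesign:
    """Which biological condition carries the heavy (K8/R10) label per experiment.

    ``experiments`` maps experiment_id -> (heavy_condition, light_condition).
    A valid reciprocal pair consists of exactly two experiments with swapped
    assignments over the same two conditions.
    """

    experiments: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        conds = self.conditions
        if len(conds) != 2:
            raise TableValidationError(
                f"labeling design must involve exactly two conditions, got {sorted(conds)}"
            )
        for exp, (heavy, light) in self.experiments.items():
            if heavy == light:
                raise TableValidationError(
                    f"experiment {exp!r} assigns the same condition to both channels"
                )

    @property
    def conditions(self) -> frozenset[str]:
        out: set[str] = set()
        for heavy, light in self.experiments.values():
            out.update((heavy, light))
        return frozenset(out)

    @property
    def experiment_ids(self) -> tuple[str, ...]:
        return tuple(self.experiments)

    @property
    def reciprocal(self) -> bool:
        if len(self.experiments) != 2:
            return False
        (h1, l1), (h2, l2) = self.experiments.values()
        return (h1, l1) == (l2, h2)

    def condition_of(self, experiment_id: str, channel: str) -> str:
        heavy, light = self.experiments[experiment_id]
        if channel == "H":
            return heavy
        if channel == "L":
            return light
        raise KeyError(f"unknown channel {channel!r}")

    def channel_of(self, experiment_id: str, condition: str) -> str:
        heavy, light = self.experiments[experiment_id]
        if condition == heavy:
            return "H"
        if condition == light:
            return "L"
        raise KeyError(f"condition {condition!r} not in experiment {experiment_id!r}")


# ---------------------------------------------------------------------------
# readers


def validate_peptide_table(table: pd.DataFrame, n_slices: int = DEFAULT_N_SLICES) -> pd.DataFrame:
    """Validate a peptide slice table already held in memory.

    Raises :class:`TableValidationError` naming the first offending 1-based
    data row; duplicates of the five-column key are an error, never summed.
    """
    missing = [c for c in PEPTIDE_COLUMNS if c not in table.columns]
    if missing:
        raise TableValidationError(f"missing column(s) {missing}")
    extra = [c for c in table.columns if c not in PEPTIDE_COLUMNS]
    if extra:
        raise TableValidationError(f"unexpected column(s) {extra}")
    table = table.reset_index(drop=True)

    bad = ~table["channel"].isin(CHANNELS)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise TableValidationError(
            f"unknown channel {table['channel'].iat[i]!r}", row=i + 1
        )
    slices = pd.to_numeric(table["slice"], errors="coerce")
    bad = slices.isna() | (slices != slices.round()) | (slices < 1) | (slices > n_slices)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise TableValidationError(
            f"slice {table['slice'].iat[i]!r} outside [1, {n_slices}]", row=i + 1
        )
    intens = pd.to_numeric(table["intensity"], errors="coerce")
    bad = intens.isna() | (intens < 0) | ~np.isfinite(intens)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise TableValidationError(
            f"intensity {table['intensity'].iat[i]!r} is not a non-negative number",
            row=i + 1,
        )
    dup = table.duplicated(subset=list(PEPTIDE_KEY), keep="first")
    if dup.any():
        i = int(np.flatnonzero(dup)[0])
        key = tuple(table.loc[i, list(PEPTIDE_KEY)])
        raise DuplicateKeyError(f"duplicate key {key}", row=i + 1)

    out = table.copy()
    out["slice"] = slices.astype(int)
    out["intensity"] = intens.astype(float)
    return out


def read_peptide_table(path: str | Path, n_slices: int = DEFAULT_N_SLICES) -> pd.DataFrame:
    """Read and validate a peptide slice TSV."""
    table = pd.read_csv(path, sep="\t", dtype={c: str for c in PEPTIDE_KEY[:4]})
    return validate_peptide_table(table, n_slices=n_slices)


def read_standards(path: str | Path) -> pd.DataFrame:
    """Read a calibration-standards TSV, sorted by slice position.

    Fewer than three standards cannot determine the log-linear calibration
    and raise :class:`UnderdeterminedError`.  Masses that do not strictly
    decrease with slice position only warn: slice jitter is tolerated by
    the least-squares fit.
    """
    table = pd.read_csv(path, sep="\t")
    return validate_standards(table)


def validate_standards(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in STANDARDS_COLUMNS if c not in table.columns]
    if missing:
        raise TableValidationError(f"missing column(s) {missing}")
    if len(table) < 3:
        raise UnderdeterminedError(
            f"need at least 3 standards to fit a calibration curve, got {len(table)}"
        )
    if (table["mass_kda"] <= 0).any():
        raise TableValidationError("standard masses must be positive")
    out = table.sort_values("slice_center", kind="stable").reset_index(drop=True)
    if not out["mass_kda"].is_monotonic_decreasing:
        warnings.warn(
            "standard masses do not strictly decrease with slice position",
            NonMonotoneStandardsWarning,
            stacklevel=2,
        )
    return out[list(STANDARDS_COLUMNS)]


def read_modules(path: str | Path) -> pd.DataFrame:
    """Read a module-annotation TSV (one protein per module)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MODULES_COLUMNS if c not in table.columns]
    if missing:
        raise TableValidationError(f"missing column(s) {missing}")
    dup = table["protein_id"].duplicated()
    if dup.any():
        i = int(np.flatnonzero(dup)[0])
        raise TableValidationError(
            f"protein {table['protein_id'].iat[i]!r} assigned to more than one module",
            row=i + 1,
        )
    return table[list(MODULES_COLUMNS)].reset_index(drop=True)


def read_design(path: str | Path) -> LabelingDesign:
    """Read a labeling-design JSON and warn if the pair is not reciprocal."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    try:
        experiments = {
            exp: (entry["heavy"], entry["light"])
            for exp, entry in payload["experiments"].items()
        }
    except (KeyError, TypeError) as err:
        raise TableValidationError(f"malformed design file: {err}") from err
    design = LabelingDesign(experiments)
    if not design.reciprocal:
        warnings.warn(
            "labeling design is not a reciprocal pair", NotReciprocalWarning, stacklevel=2
        )
    return design


# ---------------------------------------------------------------------------
# writers


def _write_tsv(table: pd.DataFrame, path: str | Path, float_cols: Sequence[str]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = table.copy()
    for col in float_cols:
        out[col] = out[col].map(_fmt)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        out.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    return path


def write_peptide_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a peptide slice TSV: zero rows omitted, key-sorted, 6 significant digits."""
    out = table.loc[table["intensity"] > 0, list(PEPTIDE_COLUMNS)]
    out = out.sort_values(list(PEPTIDE_KEY), kind="stable").reset_index(drop=True)
    return _write_tsv(out, path, float_cols=["intensity"])


def write_standards(table: pd.DataFrame, path: str | Path) -> Path:
    out = table[list(STANDARDS_COLUMNS)].sort_values("slice_center", kind="stable")
    return _write_tsv(out.reset_index(drop=True), path, float_cols=["slice_center", "mass_kda"])


def write_modules(table: pd.DataFrame, path: str | Path) -> Path:
    out = table[list(MODULES_COLUMNS)].sort_values(list(MODULES_COLUMNS), kind="stable")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.reset_index(drop=True).to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def write_design(design: LabelingDesign, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "experiments": {
            exp: {"heavy": heavy, "light": light}
            for exp, (heavy, light) in design.experiments.items()
        }
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def write_profiles(profiles: Iterable, path: str | Path) -> Path:
    """Write migration profiles as a long TSV.

    Columns are {protein_id, condition, slice, mean, sem}; the subject column
    is called ``protein_id`` whether the subject is a protein or a module.
    """
    rows = []
    for prof in profiles:
        for k, (m, s) in enumerate(zip(prof.values, prof.sem), start=1):
            rows.append((prof.subject, prof.condition, k, m, s))
    out = pd.DataFrame(rows, columns=["protein_id", "condition", "slice", "mean", "sem"])
    out = out.sort_values(["protein_id", "condition", "slice"], kind="stable")
    return _write_tsv(out.reset_index(drop=True), path, float_cols=["mean", "sem"])


def read_profiles(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "condition": str})
    missing = [c for c in ("protein_id", "condition", "slice", "mean", "sem") if c not in table.columns]
    if missing:
        raise TableValidationError(f"missing column(s) {missing}")
    return table


def write_peaks(peaks: Iterable, path: str | Path) -> Path:
    """Write detected peaks as a TSV (header-only when the list is empty)."""
    cols = [
        "subject",
        "condition",
        "center_slice",
        "apparent_mass_kda",
        "left_slice",
        "right_slice",
        "auc",
        "prominence",
    ]
    rows = [
        (
            p.subject,
            p.condition,
            p.center_slice,
            p.apparent_mass_kda,
            p.left_slice,
            p.right_slice,
            p.auc,
            p.prominence,
        )
        for p in peaks
    ]
    out = pd.DataFrame(rows, columns=cols)
    out = out.sort_values(["subject", "condition", "center_slice"], kind="stable")
    return _write_tsv(
        out.reset_index(drop=True),
        path,
        float_cols=["center_slice", "apparent_mass_kda", "auc", "prominence"],
    )


def write_enrichment(points: pd.DataFrame, path: str | Path) -> Path:
    """Write classified co-IP enrichment points as a TSV sorted by protein."""
    cols = [c for c in (
        "protein_id",
        "x_log2",
        "y_log2",
        "mean_log2",
        "n_experiments",
        "consistent",
        "interactor_class",
    ) if c in points.columns]
    out = points[cols].sort_values("protein_id", kind="stable").reset_index(drop=True)
    float_cols = [c for c in ("x_log2", "y_log2", "mean_log2") if c in cols]
    tmp = out.copy()
    for col in float_cols:
        tmp[col] = tmp[col].map(lambda v: "" if pd.isna(v) else _fmt(v))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def write_curve(curve, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "a": curve.intercept_a,
        "b": curve.slope_b,
        "residual_sd": curve.residual_sd,
        "n": curve.n_standards,
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_curve(path: str | Path):
    from .calibration import CalibrationCurve

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return CalibrationCurve(
        intercept_a=float(payload["a"]),
        slope_b=float(payload["b"]),
        residual_sd=float(payload["residual_sd"]),
        n_standards=int(payload["n"]),
    )
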