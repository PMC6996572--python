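"""Exceptions and warning categories shared across the package."""

from __future__ import annotations


class ComplexomeError(Exception):
    """Base class for all package-specific errors."""


class TableValidationError(ComplexomeError, ValueError):
    """An on-disk table violates its schema or invariants.

    ``row`` is the 1-based data-row number (excluding the header) of the
    first offending row, when the problem is attributable to a single row.
    """

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)
        self.row = row


class DuplicateKeyError(TableValidationError):
    """Two rows share the same (experiment, channel, protein, peptide, slice) key."""


class UnderdeterminedError(ComplexomeError, ValueError):
    """Too few calibration standards to fit the slice-to-mass curve."""


class InvertedGelOrientationError(ComplexomeError, ValueError):
    """The fitted calibration slope is non-negative: mass must decrease down the gel."""


class EmptyModuleError(ComplexomeError, ValueError):
    """No member protein of an annotated module was observed in the data."""


class NotReciprocalWarning(UserWarning):
    """The two experiments of a labeling design do not swap heavy/light conditions."""


class NonMonotoneStandardsWarning(UserWarning):
    """Standard masses do not strictly decrease with slice position (jitter tolerated)."""


class ClippedPeakWarning(UserWarning):
    """A species' migration center falls outside the lane and was clipped to its edge."""


class DegenerateWindowWarning(UserWarning):
    """A mass window collapsed below one slice and was widened to one slice."""
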