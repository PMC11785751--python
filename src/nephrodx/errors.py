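"""Typed exceptions shared across the package.

Undefined quantities raise rather than propagating NaN, so that a malformed
cohort surfaces at the point of computation instead of in a downstream report.
"""

from __future__ import annotations


class NephrodxError(Exception):
    """Base class for all package errors."""


class SchemaError(NephrodxError, ValueError):
    """An input table is missing a required column or has an unusable layout."""


class CohortValidationError(NephrodxError, ValueError):
    """One or more rows of an input table violate a field invariant.

    ``errors`` holds ``(row_number, message)`` pairs; row numbers are 1-based
    positions in the source file (header excluded).
    """

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"row {n}: {msg}" for n, msg in self.errors[:20])
        more = "" if len(self.errors) <= 20 else f" (+{len(self.errors) - 20} more)"
        super().__init__(f"{len(self.errors)} invalid row(s): {lines}{more}")


class DataError(NephrodxError, ValueError):
    """A value encountered mid-computation is impossible (e.g. nonpositive baseline)."""


class UndefinedMetricError(NephrodxError, ValueError):
    """A diagnostic metric has an empty denominator."""


class DegenerateTableError(NephrodxError, ValueError):
    """A 2x2 comparison table has a zero marginal, so the chi-square test is undefined."""


class ScenarioError(NephrodxError, ValueError):
    """A simulation scenario is internally contradictory."""
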