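"""Algorithm configuration.

All decision thresholds of the rule engine live here so that the computerized
algorithm and the gold-standard adjudicator provably share one parameter set.

Defaults encode the KDIGO-derived study rules: an alerting creatinine above
1.3 mg/dL, AKI at a 1.5-fold rise over baseline, CKD at eGFR below
60 mL/min/1.73 m^2 sustained beyond 90 days, and a 7-day acute lookback
window for the preferred baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

WindowMode = Literal["hierarchical", "any_window"]


@dataclass(frozen=True)
class AlgorithmConfig:
    """Thresholds and switches shared by both diagnostic rule engines.

    Parameters
    ----------
    scr_abnormal_threshold
        Serum creatinine (mg/dL) above which a measurement is "abnormal" and
        triggers assessment. Strict: a value equal to the threshold does not alert.
    aki_ratio_threshold
        Fold-rise over baseline defining AKI.
    egfr_threshold
        eGFR (mL/min/1.73 m^2) below which renal function is abnormal. Strict.
    chronicity_days
        Days a low eGFR must predate the index measurement to count as chronic.
    acute_window_days
        Extent of the acute baseline lookback window (days before index).
    ratio_strict
        ``False`` (default): AKI when ratio >= threshold. ``True``: ratio > threshold.
    window_mode
        ``hierarchical``: prefer the 1..7-day window, then 8..90 days, then the
        nearest record beyond 90 days. ``any_window``: take the lowest candidate
        across all windows (sensitivity-analysis alternative).
    race_coefficient
        Apply the 1.159 multiplier of the 2009 CKD-EPI equation. Off by default.
    exclude_dialysis
        Skip AKI assessment for patients flagged as on dialysis. Off by default so
        the documented dialysis false-positive mechanism is reproducible.
    """

    scr_abnormal_threshold: float = 1.3
    aki_ratio_threshold: float = 1.5
    egfr_threshold: float = 60.0
    chronicity_days: int = 90
    acute_window_days: int = 7
    ratio_strict: bool = False
    window_mode: WindowMode = "hierarchical"
    race_coefficient: bool = False
    exclude_dialysis: bool = False

    def __post_init__(self) -> None:
        for name in ("scr_abnormal_threshold", "aki_ratio_threshold", "egfr_threshold",
                     "chronicity_days", "acute_window_days"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.acute_window_days < self.chronicity_days:
            raise ValueError("acute_window_days must be smaller than chronicity_days")
        if self.window_mode not in ("hierarchical", "any_window"):
            raise ValueError(f"unknown window_mode {self.window_mode!r}")

    @classmethod
    def strict_rules(cls) -> "AlgorithmConfig":
        """The closest literal reading of the published method description.

        Pins the strict ratio comparison (">1.5 times"), hierarchical window
        precedence and no race coefficient.
        """
        return cls(ratio_strict=True, window_mode="hierarchical", race_coefficient=False)

    def with_overrides(self, **kwargs) -> "AlgorithmConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "scr_abnormal_threshold": self.scr_abnormal_threshold,
            "aki_ratio_threshold": self.aki_ratio_threshold,
            "egfr_threshold": self.egfr_threshold,
            "chronicity_days": self.chronicity_days,
            "acute_window_days": self.acute_window_days,
            "ratio_strict": self.ratio_strict,
            "window_mode": self.window_mode,
            "race_coefficient": self.race_coefficient,
            "exclude_dialysis": self.exclude_dialysis,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlgorithmConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)
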