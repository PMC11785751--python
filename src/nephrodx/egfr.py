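"""Estimated glomerular filtration rate via the 2009 CKD-EPI creatinine equation.

    eGFR = 141 * min(Scr/kappa, 1)^alpha * max(Scr/kappa, 1)^-1.209
           * 0.993^age * 1.018 [if female] * 1.159 [if race coefficient applied]

with kappa = 0.7 (female) / 0.9 (male) and alpha = -0.329 (female) / -0.411
(male); Scr in mg/dL, age in years, eGFR in mL/min/1.73 m^2. The race
coefficient is off by default and exposed as a switch. Age enters as a real
number of years (no truncation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import AlgorithmConfig

KAPPA = {"female": 0.7, "male": 0.9}
ALPHA = {"female": -0.329, "male": -0.411}
FEMALE_MULTIPLIER = 1.018
RACE_MULTIPLIER = 1.159


@dataclass(frozen=True)
class EgfrResult:
    """An eGFR value together with an echo of the inputs that produced it."""

    egfr: float
    scr: float
    age_years: float
    sex: str
    race_coefficient_applied: bool


def _egfr_value(scr: float, age_years: float, sex: str, race_coefficient: bool) -> float:
    kappa = KAPPA[sex]
    ratio = scr / kappa
    value = (141.0
             * min(ratio, 1.0) ** ALPHA[sex]
             * max(ratio, 1.0) ** -1.209
             * 0.993 ** age_years)
    if sex == "female":
        value *= FEMALE_MULTIPLIER
    if race_coefficient:
        value *= RACE_MULTIPLIER
    return value


def ckd_epi_egfr(scr: float, age_years: float, sex: str,
                 race_coefficient: bool = False) -> EgfrResult:
    """Compute eGFR (mL/min/1.73 m^2) from creatinine (mg/dL), age and sex.

    Raises ``ValueError`` for nonpositive/nonfinite creatinine, negative age,
    or an unknown sex label.
    """
    if sex not in KAPPA:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if not (math.isfinite(scr) and scr > 0):
        raise ValueError(f"scr must be positive and finite, got {scr!r}")
    if not (math.isfinite(age_years) and age_years >= 0):
        raise ValueError(f"age_years must be nonnegative and finite, got {age_years!r}")
    return EgfrResult(egfr=_egfr_value(scr, age_years, sex, race_coefficient),
                      scr=scr, age_years=age_years, sex=sex,
                      race_coefficient_applied=race_coefficient)


def is_abnormal_egfr(egfr: float, config: AlgorithmConfig) -> bool:
    """True iff eGFR is strictly below the configured threshold (default 60)."""
    if not math.isfinite(egfr):
        raise ValueError(f"egfr must be finite, got {egfr!r}")
    return egfr < config.egfr_threshold


def scr_for_egfr(target_egfr: float, age_years: float, sex: str,
                 race_coefficient: bool = False) -> float:
    """Creatinine (mg/dL) at which the equation returns ``target_egfr``.

    Closed-form inversion of the monotone equation; used by the cohort
    simulator to place baselines safely on one side of the eGFR threshold.
    """
    if target_egfr <= 0:
        raise ValueError("target_egfr must be positive")
    kappa = KAPPA[sex]
    scale = 141.0 * 0.993 ** age_years
    if sex == "female":
        scale *= FEMALE_MULTIPLIER
    if race_coefficient:
        scale *= RACE_MULTIPLIER
    frac = target_egfr / scale
    if frac < 1.0:  # scr above kappa (the -1.209 branch)
        return kappa * frac ** (-1.0 / 1.209)
    return kappa * frac ** (1.0 / ALPHA[sex])
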