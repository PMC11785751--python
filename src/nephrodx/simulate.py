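"""Synthetic cohort generator with ground-truth AKI/CKD labels.

The generator's job is structural, not distributional: it emulates the lab
trajectories that make each of the four documented error mechanisms of the
computerized algorithm reproducible without any real data —

``PREADMISSION_AKI``
    the creatinine rise completed before admission, so every value the peak's
    acute lookback window can see is already elevated (false negative);
``DENSE_TESTING``
    a slow in-hospital rise with daily tests, so the lowest value within
    7 days of the peak is itself mid-rise and the ratio stays below 1.5
    (false negative), while a reviewer comparing against the pre-admission
    baseline still calls the event;
``DIALYSIS_FLUCTUATION``
    an inter-dialytic creatinine sawtooth whose trough/peak ratio crosses the
    1.5-fold rule with no true injury (false positive);
``MISSING_HISTORY``
    true CKD with no laboratory records in the database before admission, so
    chronicity can never be established (false negative for CKD).

Everything else is a clean trajectory: log-normal baseline creatinine,
exponential outpatient test cadence, daily in-hospital tests, multiplicative
log-normal measurement noise. Mechanism fractions default to the empirical
rates of the validation study, so the expected sensitivity/specificity of the
algorithm against ground truth is computable in closed form from the scenario
(see docs/methods.md).

Reproducibility: each patient draws from an independent substream spawned
from the master seed, so cohorts are byte-identical across runs and
insensitive to generation order.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Demographics, HospitalEpisode, LabRecord, PatientTimeline, write_cohort
from .egfr import scr_for_egfr
from .errors import ScenarioError


class Mechanism(str, enum.Enum):
    DIALYSIS_FLUCTUATION = "DIALYSIS_FLUCTUATION"
    PREADMISSION_AKI = "PREADMISSION_AKI"
    DENSE_TESTING = "DENSE_TESTING"
    MISSING_HISTORY = "MISSING_HISTORY"
    CLEAN = "CLEAN"


@dataclass(frozen=True)
class GroundTruth:
    patient_id: str
    aki: bool
    ckd: bool
    mechanisms: frozenset[Mechanism]

    def __post_init__(self) -> None:
        if Mechanism.MISSING_HISTORY in self.mechanisms and not self.ckd:
            raise ValueError("MISSING_HISTORY implies true CKD")
        if Mechanism.DIALYSIS_FLUCTUATION in self.mechanisms and self.aki:
            raise ValueError("DIALYSIS_FLUCTUATION implies no true AKI")
        if (Mechanism.PREADMISSION_AKI in self.mechanisms
                or Mechanism.DENSE_TESTING in self.mechanisms) and not self.aki:
            raise ValueError("AKI mechanisms require a true AKI label")


# --- trajectory constants (named so the methods note can cite them) ---------

BASELINE_MEDIAN_SCR = {"non_ckd": 1.0, "ckd": 2.0}   # mg/dL
BASELINE_SIGMA_LOG = 0.15
DIALYSIS_MEDIAN_SCR = 6.0                             # pre-dialysis (peak-phase)
DIALYSIS_SIGMA_LOG = 0.2
NOISE_SIGMA_LOG = 0.03                                # per-measurement noise
OUTPATIENT_MEAN_INTERVAL_DAYS = 45.0
HISTORY_SPAN_DAYS = 360
ANCHOR_OFFSET_RANGE = (-200, -120)                    # guarantees >90-day evidence
EPISODE_LENGTH_RANGE = (5, 20)                        # days, inclusive
AKI_RISE_FACTOR_RANGE = (1.6, 4.0)
AKI_RISE_DAYS_RANGE = (2, 5)
DENSE_RISE_FACTOR_RANGE = (1.6, 1.75)
DENSE_RISE_DAYS = 15                                  # rise spread over 15 daily steps
DENSE_MIN_BASELINE_SCR = 0.85                         # keeps the obscured peak alertable
PREADMIT_RISE_OFFSETS = (-14, -10)                    # rise completed >7 d pre-admission
SAWTOOTH_ALERT_TROUGH_RATIO = (0.50, 0.65)            # trips the 1.5-fold rule
SAWTOOTH_QUIET_TROUGH_RATIO = (0.85, 0.95)            # does not
MALE_FRACTION = 0.631
AGE_MEAN, AGE_SD = 73.0, 14.9
CLINICIAN_AKI_ACCURACY = 0.570
CLINICIAN_CKD_ACCURACY = 0.736
MIN_ALERTABLE_PEAK = 1.45                             # > abnormal threshold + noise margin
CKD_BASELINE_MAX_EGFR = 48.0                          # clamp: truly chronic kidneys
NONCKD_BASELINE_MIN_EGFR = 62.0                       # clamp: truly normal kidneys
NONCKD_NOISE_GUARD = 1.12                             # headroom for 4-sigma noise


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for a simulated cohort.

    Mechanism fractions default to the validation study's empirical rates:
    AKI prevalence 443/1551, CKD prevalence 1031/1551, 45/443 AKI events
    completed pre-admission, 19/443 obscured by dense testing, 55/1031 CKD
    cases without database history, 13/1108 non-AKI patients with an
    alert-triggering dialysis sawtooth, 20% of patients on dialysis overall,
    56.6% admitted from the emergency department.
    """

    n_patients: int = 100
    aki_prevalence: float = 0.286
    ckd_prevalence: float = 1031 / 1551
    dialysis_fraction: float = 0.200
    preadmission_aki_fraction: float = 45 / 443     # of AKI cases
    dense_testing_fraction: float = 19 / 443        # of AKI cases
    missing_history_fraction: float = 55 / 1031     # of CKD cases
    dialysis_alert_fraction: float = 13 / 1108      # of non-AKI cases
    ed_fraction: float = 0.566
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ScenarioError("n_patients must be at least 1")
        for name in ("aki_prevalence", "ckd_prevalence", "dialysis_fraction",
                     "preadmission_aki_fraction", "dense_testing_fraction",
                     "missing_history_fraction", "dialysis_alert_fraction",
                     "ed_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ScenarioError(f"{name} must lie in [0, 1], got {v!r}")
        if self.preadmission_aki_fraction + self.dense_testing_fraction > 1.0:
            raise ScenarioError("AKI mechanism fractions must sum to at most 1")
        if self.aki_prevalence == 0.0 and (self.preadmission_aki_fraction > 0
                                           or self.dense_testing_fraction > 0):
            raise ScenarioError("AKI mechanism fractions require a nonzero AKI prevalence")
        if self.ckd_prevalence == 0.0 and self.missing_history_fraction > 0:
            raise ScenarioError("missing_history_fraction requires a nonzero CKD prevalence")

    def clean(self) -> "ScenarioConfig":
        """The same cohort with every confounder fraction at zero."""
        return replace(self, preadmission_aki_fraction=0.0, dense_testing_fraction=0.0,
                       missing_history_fraction=0.0, dialysis_alert_fraction=0.0)

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ScenarioError(f"unknown scenario field(s): {sorted(unknown)}")
        return cls(**d)


STUDY_START = date(2020, 3, 1)


def _noise(rng: np.random.Generator) -> float:
    return float(np.exp(rng.normal(0.0, NOISE_SIGMA_LOG)))


def _is_dialysis_trough_day(day: date) -> bool:
    # thrice-weekly schedule pinned to the calendar: post-dialysis troughs
    return day.toordinal() % 7 in (1, 3, 5)


def _sawtooth(day: date, peak: float, trough_ratio: float) -> float:
    return peak * trough_ratio if _is_dialysis_trough_day(day) else peak


def simulate_patient(scenario: ScenarioConfig, rng: np.random.Generator,
                     patient_id: str = "P0") -> tuple[PatientTimeline, GroundTruth]:
    """Draw one patient timeline and its ground truth from ``rng``.

    Identical generator state yields identical output.
    """
    # --- labels and mechanisms -------------------------------------------
    aki = bool(rng.random() < scenario.aki_prevalence)
    ckd = bool(rng.random() < scenario.ckd_prevalence)
    mechanisms: set[Mechanism] = set()
    on_dialysis = False
    if aki:
        u = rng.random()
        if u < scenario.preadmission_aki_fraction:
            mechanisms.add(Mechanism.PREADMISSION_AKI)
        elif u < scenario.preadmission_aki_fraction + scenario.dense_testing_fraction:
            mechanisms.add(Mechanism.DENSE_TESTING)
    else:
        if rng.random() < scenario.dialysis_alert_fraction:
            mechanisms.add(Mechanism.DIALYSIS_FLUCTUATION)
            ckd = True
            on_dialysis = True
    if (ckd and Mechanism.DIALYSIS_FLUCTUATION not in mechanisms
            and Mechanism.PREADMISSION_AKI not in mechanisms
            and rng.random() < scenario.missing_history_fraction):
        mechanisms.add(Mechanism.MISSING_HISTORY)
    if not mechanisms:
        mechanisms.add(Mechanism.CLEAN)

    # --- demographics -----------------------------------------------------
    sex = "male" if rng.random() < MALE_FRACTION else "female"
    age = float(np.clip(rng.normal(AGE_MEAN, AGE_SD), 21.0, 105.0))
    source = "ED" if rng.random() < scenario.ed_fraction else "OPD"
    if not on_dialysis and ckd and not aki and scenario.dialysis_fraction > 0:
        denom = (1.0 - scenario.aki_prevalence) * scenario.ckd_prevalence
        p_dial = min(1.0, scenario.dialysis_fraction / denom) if denom > 0 else 0.0
        on_dialysis = bool(rng.random() < p_dial)
    demo = Demographics(patient_id=patient_id, sex=sex, age_years=round(age, 1),
                        on_dialysis=on_dialysis, source=source)

    # --- baseline creatinine, clamped to the correct side of the threshold -
    dialysis_profile = on_dialysis and not aki
    if Mechanism.DIALYSIS_FLUCTUATION in mechanisms:
        trough_ratio = float(rng.uniform(*SAWTOOTH_ALERT_TROUGH_RATIO))
    else:
        trough_ratio = float(rng.uniform(*SAWTOOTH_QUIET_TROUGH_RATIO))
    if dialysis_profile:
        floor = scr_for_egfr(45.0, age, sex) / trough_ratio * 1.1
        baseline = max(float(rng.lognormal(math.log(DIALYSIS_MEDIAN_SCR),
                                           DIALYSIS_SIGMA_LOG)), floor)
    elif ckd:
        baseline = max(float(rng.lognormal(math.log(BASELINE_MEDIAN_SCR["ckd"]),
                                           BASELINE_SIGMA_LOG)),
                       scr_for_egfr(CKD_BASELINE_MAX_EGFR, age, sex))
    else:
        baseline = min(float(rng.lognormal(math.log(BASELINE_MEDIAN_SCR["non_ckd"]),
                                           BASELINE_SIGMA_LOG)),
                       scr_for_egfr(NONCKD_BASELINE_MIN_EGFR, age, sex) / NONCKD_NOISE_GUARD)

    # --- AKI event shape --------------------------------------------------
    if Mechanism.DENSE_TESTING in mechanisms:
        baseline = max(baseline, DENSE_MIN_BASELINE_SCR)
        rise_factor = float(rng.uniform(*DENSE_RISE_FACTOR_RANGE))
        rise_days = DENSE_RISE_DAYS
    elif aki:
        rise_factor = float(rng.uniform(*AKI_RISE_FACTOR_RANGE))
        rise_days = int(rng.integers(AKI_RISE_DAYS_RANGE[0], AKI_RISE_DAYS_RANGE[1] + 1))
    else:
        rise_factor, rise_days = 1.0, 0
    if aki:
        rise_factor = max(rise_factor, MIN_ALERTABLE_PEAK / baseline)

    # --- dates ------------------------------------------------------------
    admit = STUDY_START + timedelta(days=int(rng.integers(0, 240)))
    if Mechanism.DENSE_TESTING in mechanisms:
        length = int(rng.integers(DENSE_RISE_DAYS + 3, EPISODE_LENGTH_RANGE[1] + 1))
        rise_start = 1
    elif aki and Mechanism.PREADMISSION_AKI not in mechanisms:
        length = int(rng.integers(max(8, rise_days + 3), EPISODE_LENGTH_RANGE[1] + 1))
        rise_start = int(rng.integers(1, length - rise_days))
    else:
        length = int(rng.integers(EPISODE_LENGTH_RANGE[0], EPISODE_LENGTH_RANGE[1] + 1))
        rise_start = 0
    episode = HospitalEpisode(patient_id=patient_id, admit_date=admit,
                              discharge_date=admit + timedelta(days=length - 1))

    # --- pre-admission value model ---------------------------------------
    pre_lo, pre_hi = PREADMIT_RISE_OFFSETS

    def pre_value(offset: int) -> float:
        if dialysis_profile:
            return _sawtooth(admit + timedelta(days=offset), baseline, trough_ratio)
        if Mechanism.PREADMISSION_AKI in mechanisms:
            if offset <= pre_lo:
                return baseline
            if offset >= pre_hi:
                return baseline * rise_factor
            return baseline * rise_factor ** ((offset - pre_lo) / (pre_hi - pre_lo))
        return baseline

    history_offsets: list[int] = []
    if Mechanism.MISSING_HISTORY not in mechanisms:
        t = -float(HISTORY_SPAN_DAYS)
        while True:
            t += float(rng.exponential(OUTPATIENT_MEAN_INTERVAL_DAYS))
            if t > -1.0:
                break
            history_offsets.append(int(round(t)))
        history_offsets.append(int(rng.integers(ANCHOR_OFFSET_RANGE[0],
                                                ANCHOR_OFFSET_RANGE[1] + 1)))
        if Mechanism.PREADMISSION_AKI in mechanisms:
            history_offsets.extend(range(pre_lo, pre_hi + 1))  # the outpatient event
            # the visit that led to admission: an elevated value inside the
            # acute window of any in-episode index, masking the true baseline
            history_offsets.append(int(rng.integers(-4, 0)))
        history_offsets = sorted(set(history_offsets))

    # --- in-episode value model (daily tests) ----------------------------
    def episode_value(offset: int) -> float:
        if dialysis_profile:
            return _sawtooth(admit + timedelta(days=offset), baseline, trough_ratio)
        if Mechanism.PREADMISSION_AKI in mechanisms:
            return baseline * rise_factor   # sustained, un-recovered injury
        if aki:
            if offset < rise_start:
                return baseline
            if offset <= rise_start + rise_days:
                return baseline * rise_factor ** ((offset - rise_start) / rise_days)
            return max(baseline, baseline * rise_factor * 0.75 ** (offset - rise_start - rise_days))
        return baseline

    labs = [LabRecord(collected_at=admit + timedelta(days=off),
                      scr=round(pre_value(off) * _noise(rng), 3),
                      patient_id=patient_id)
            for off in history_offsets]
    labs += [LabRecord(collected_at=admit + timedelta(days=off),
                       scr=round(episode_value(off) * _noise(rng), 3),
                       patient_id=patient_id)
             for off in range(length)]

    clinician = (aki if rng.random() < CLINICIAN_AKI_ACCURACY else not aki,
                 ckd if rng.random() < CLINICIAN_CKD_ACCURACY else not ckd)

    timeline = PatientTimeline(demographics=demo, labs=labs, episodes=[episode],
                               clinician_dx=clinician)
    truth = GroundTruth(patient_id=patient_id, aki=aki, ckd=ckd,
                        mechanisms=frozenset(mechanisms))
    return timeline, truth


def simulate_cohort(scenario: ScenarioConfig,
                    ) -> tuple[list[PatientTimeline], list[GroundTruth]]:
    """``n_patients`` independent draws from per-patient substreams of the seed."""
    streams = np.random.SeedSequence(scenario.seed).spawn(scenario.n_patients)
    timelines: list[PatientTimeline] = []
    truths: list[GroundTruth] = []
    width = max(4, len(str(scenario.n_patients)))
    for i, ss in enumerate(streams):
        tl, gt = simulate_patient(scenario, np.random.default_rng(ss),
                                  patient_id=f"SIM{i:0{width}d}")
        timelines.append(tl)
        truths.append(gt)
    return timelines, truths


def truth_frame(truths: Sequence[GroundTruth],
                timelines: Optional[Sequence[PatientTimeline]] = None) -> pd.DataFrame:
    """Ground truth as a DataFrame keyed like the diagnosis tables."""
    admit = {}
    if timelines is not None:
        admit = {tl.patient_id: tl.episodes[0].admit_date.isoformat()
                 for tl in timelines if tl.episodes}
    rows = []
    for gt in truths:
        row = {"patient_id": gt.patient_id,
               "aki": int(gt.aki), "ckd": int(gt.ckd),
               "mechanisms": "|".join(sorted(m.value for m in gt.mechanisms))}
        if admit:
            row["admit_date"] = admit.get(gt.patient_id, "")
        rows.append(row)
    cols = ["patient_id"] + (["admit_date"] if admit else []) + ["aki", "ckd", "mechanisms"]
    return pd.DataFrame(rows, columns=cols)


def write_simulated_cohort(timelines: Sequence[PatientTimeline],
                           truths: Sequence[GroundTruth], out_dir) -> dict[str, Path]:
    """Cohort CSVs in the standard dialect plus ground_truth.csv."""
    paths = write_cohort(timelines, out_dir)
    p = Path(out_dir) / "ground_truth.csv"
    truth_frame(truths, timelines).to_csv(p, index=False)
    paths["ground_truth"] = p
    return paths


# ---------------------------------------------------------------------------
# Hand-built demonstration cohort
# ---------------------------------------------------------------------------

def demo_cohort() -> tuple[list[PatientTimeline], list[GroundTruth]]:
    """Six canonical patients, one per behaviour class, with exact values.

    DEMO1 clean in-hospital AKI; DEMO2 clean non-AKI; DEMO3 first-ever
    abnormal creatinine with no history (assumed-normal AKI); DEMO4 dialysis
    sawtooth false positive; DEMO5 dense-testing false negative; DEMO6
    missing-history CKD false negative. Every number is chosen so the rule
    walk can be done by hand (see the test suite's golden expectations).
    """
    def d(iso: str) -> date:
        return date.fromisoformat(iso)

    def patient(pid, sex, age, dialysis, labs, admit, discharge):
        demo = Demographics(patient_id=pid, sex=sex, age_years=age,
                            on_dialysis=dialysis, source="ED")
        return PatientTimeline(
            demographics=demo,
            labs=[LabRecord(collected_at=d(day), scr=v, patient_id=pid)
                  for day, v in labs],
            episodes=[HospitalEpisode(patient_id=pid, admit_date=d(admit),
                                      discharge_date=d(discharge))],
        )

    timelines = [
        patient("DEMO1", "male", 70, False,
                [("2020-01-03", 1.0), ("2020-05-02", 1.0),
                 ("2020-06-01", 1.0), ("2020-06-02", 1.1), ("2020-06-03", 1.6),
                 ("2020-06-04", 2.2), ("2020-06-05", 2.0)],
                "2020-06-01", "2020-06-10"),
        patient("DEMO2", "male", 70, False,
                [("2020-02-22", 1.2), ("2020-05-12", 1.2),
                 ("2020-06-01", 1.2), ("2020-06-03", 1.35), ("2020-06-05", 1.25)],
                "2020-06-01", "2020-06-08"),
        patient("DEMO3", "male", 70, False,
                [("2020-06-01", 1.8), ("2020-06-02", 1.6)],
                "2020-06-01", "2020-06-07"),
        patient("DEMO4", "male", 60, True,
                [("2020-01-15", 6.0), ("2020-02-20", 3.2),
                 ("2020-06-01", 3.2), ("2020-06-02", 6.0), ("2020-06-03", 3.1),
                 ("2020-06-04", 6.2), ("2020-06-05", 3.3)],
                "2020-06-01", "2020-06-10"),
        patient("DEMO5", "male", 70, False,
                [("2020-01-03", 0.95), ("2020-05-22", 1.0)]
                + [((d("2020-06-01") + timedelta(days=o)).isoformat(),
                    round(1.05 ** o, 3)) for o in range(15)],
                "2020-06-01", "2020-06-16"),
        patient("DEMO6", "female", 75, False,
                [("2020-06-02", 2.4), ("2020-06-03", 2.5),
                 ("2020-06-04", 2.4), ("2020-06-05", 2.35)],
                "2020-06-01", "2020-06-06"),
    ]
    truths = [
        GroundTruth("DEMO1", aki=True, ckd=False, mechanisms=frozenset({Mechanism.CLEAN})),
        GroundTruth("DEMO2", aki=False, ckd=False, mechanisms=frozenset({Mechanism.CLEAN})),
        GroundTruth("DEMO3", aki=True, ckd=False, mechanisms=frozenset({Mechanism.CLEAN})),
        GroundTruth("DEMO4", aki=False, ckd=True,
                    mechanisms=frozenset({Mechanism.DIALYSIS_FLUCTUATION})),
        GroundTruth("DEMO5", aki=True, ckd=False,
                    mechanisms=frozenset({Mechanism.DENSE_TESTING})),
        GroundTruth("DEMO6", aki=False, ckd=True,
                    mechanisms=frozenset({Mechanism.MISSING_HISTORY})),
    ]
    return timelines, truths
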