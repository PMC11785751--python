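"""The computerized renal-impairment algorithm.

Per hospitalization the engine:

1. picks the *index* creatinine — the highest in-episode value above the
   abnormal threshold (1.3 mg/dL), earliest date on ties;
2. selects a *baseline* by hierarchical lookback from the index date:
   the lowest value 1–7 days before, else the lowest value 8–90 days before,
   else the nearest (latest) value more than 90 days before, else the baseline
   is assumed normal;
3. calls AKI when index/baseline meets the 1.5-fold threshold (assumed-normal
   baseline implies AKI, so that a first-ever abnormal creatinine is never a
   silent miss);
4. independently, calls CKD when the most recent eGFR evidence more than
   90 days before the first in-episode abnormal-eGFR date is itself below
   60 mL/min/1.73 m^2.

Every verdict carries machine-readable rationale codes so that evaluation can
attribute errors to mechanisms.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date
from typing import Optional, Sequence

from .cohort import HospitalEpisode, LabRecord, PatientTimeline, window_records
from .config import AlgorithmConfig
from .egfr import _egfr_value, is_abnormal_egfr
from .errors import DataError


class BaselineWindow(str, enum.Enum):
    D1_7 = "D1_7"
    D8_90 = "D8_90"
    D_GT90 = "D_GT90"
    NONE = "NONE"


class AKIRationale(str, enum.Enum):
    RATIO_MET = "RATIO_MET"
    RATIO_NOT_MET = "RATIO_NOT_MET"
    NO_PRIOR_RECORDS = "NO_PRIOR_RECORDS"


class CKDRationale(str, enum.Enum):
    PRIOR_LOW_EGFR_BEYOND_90D = "PRIOR_LOW_EGFR_BEYOND_90D"
    PRIOR_NORMAL_EGFR_BEYOND_90D = "PRIOR_NORMAL_EGFR_BEYOND_90D"
    NO_PRIOR_RECORDS = "NO_PRIOR_RECORDS"


@dataclass(frozen=True)
class BaselineResult:
    """The selected baseline creatinine, or the assumed-normal sentinel.

    ``value is None`` (with window ``NONE`` and no source date) means no prior
    record existed and the baseline is assumed normal; no fabricated numeric
    creatinine is ever used in a ratio.
    """

    value: Optional[float]
    window: BaselineWindow
    source_date: Optional[date]

    def __post_init__(self) -> None:
        sentinel = self.value is None
        if sentinel != (self.window is BaselineWindow.NONE) or sentinel != (self.source_date is None):
            raise ValueError("value, window and source_date must be jointly present or absent")

    @property
    def assumed_normal(self) -> bool:
        return self.value is None

    @classmethod
    def assumed_normal_result(cls) -> "BaselineResult":
        return cls(value=None, window=BaselineWindow.NONE, source_date=None)


@dataclass(frozen=True)
class AKIAssessment:
    positive: bool
    index_date: date
    index_scr: float
    baseline: BaselineResult
    ratio: Optional[float]
    rationale: AKIRationale


@dataclass(frozen=True)
class CKDAssessment:
    positive: bool
    index_date: date
    evidence_date: Optional[date]
    rationale: CKDRationale


@dataclass(frozen=True)
class HospitalizationDiagnosis:
    """Binary AKI and CKD verdicts for one hospitalization.

    Either assessment is ``None`` when its gate never opened (no in-episode
    creatinine above the abnormal threshold for AKI; no in-episode abnormal
    eGFR for CKD). Downstream evaluation treats an absent assessment as a
    negative call (no alert raised).
    """

    patient_id: str
    episode: HospitalEpisode
    aki: Optional[AKIAssessment]
    ckd: Optional[CKDAssessment]


# ---------------------------------------------------------------------------
# Steps
# ---------------------------------------------------------------------------

def _lowest(records: Sequence[LabRecord]) -> LabRecord:
    # lowest value; earliest date on value ties (deterministic under permutation)
    return min(records, key=lambda r: (r.scr, r.collected_at))


def _nearest_before(records: Sequence[LabRecord]) -> LabRecord:
    # latest date; lowest value on same-day ties
    latest = max(r.collected_at for r in records)
    return _lowest([r for r in records if r.collected_at == latest])


def find_index_scr(timeline: PatientTimeline, episode: HospitalEpisode,
                   config: AlgorithmConfig) -> Optional[tuple[date, float]]:
    """The highest in-episode creatinine above the abnormal threshold.

    Ties broken by earliest date; ``None`` when no in-episode value exceeds
    the threshold (the patient raises no alert for this hospitalization).
    """
    best: Optional[LabRecord] = None
    for r in timeline.labs:
        if episode.contains(r.collected_at) and r.scr > config.scr_abnormal_threshold:
            if best is None or r.scr > best.scr:
                best = r
    if best is None:
        return None
    return best.collected_at, best.scr


def select_baseline(timeline: PatientTimeline, index_date: date,
                    config: AlgorithmConfig) -> BaselineResult:
    """Windowed baseline selection relative to the index date.

    Hierarchical mode prefers the acute window (lowest value 1..7 days
    before), then the subacute window (lowest value 8..90 days before), then
    the nearest record strictly older than 90 days; with no prior record at
    all the baseline is assumed normal. ``any_window`` mode instead returns
    the lowest candidate across all three windows (ties resolved in
    hierarchical order).
    """
    acute = window_records(timeline, index_date, 1, config.acute_window_days)
    subacute = window_records(timeline, index_date,
                              config.acute_window_days + 1, config.chronicity_days)
    older = [r for r in timeline.labs
             if (index_date - r.collected_at).days > config.chronicity_days]

    candidates: list[BaselineResult] = []
    if acute:
        rec = _lowest(acute)
        candidates.append(BaselineResult(rec.scr, BaselineWindow.D1_7, rec.collected_at))
    if subacute:
        rec = _lowest(subacute)
        candidates.append(BaselineResult(rec.scr, BaselineWindow.D8_90, rec.collected_at))
    if older:
        rec = _nearest_before(older)
        candidates.append(BaselineResult(rec.scr, BaselineWindow.D_GT90, rec.collected_at))

    if not candidates:
        return BaselineResult.assumed_normal_result()
    if config.window_mode == "hierarchical":
        return candidates[0]
    return min(candidates, key=lambda b: b.value)  # any_window; list order breaks ties


def assess_aki(index_date: date, index_scr: float, baseline: BaselineResult,
               config: AlgorithmConfig) -> AKIAssessment:
    """Binary AKI call from the index value and the selected baseline."""
    if baseline.assumed_normal:
        return AKIAssessment(positive=True, index_date=index_date, index_scr=index_scr,
                             baseline=baseline, ratio=None,
                             rationale=AKIRationale.NO_PRIOR_RECORDS)
    if baseline.value <= 0:
        raise DataError(f"baseline creatinine must be positive, got {baseline.value!r}")
    ratio = index_scr / baseline.value
    if config.ratio_strict:
        positive = ratio > config.aki_ratio_threshold
    else:
        positive = ratio >= config.aki_ratio_threshold
    rationale = AKIRationale.RATIO_MET if positive else AKIRationale.RATIO_NOT_MET
    return AKIAssessment(positive=positive, index_date=index_date, index_scr=index_scr,
                         baseline=baseline, ratio=ratio, rationale=rationale)


def beyond_window_evidence(timeline: PatientTimeline, index_date: date,
                           config: AlgorithmConfig) -> Optional[LabRecord]:
    """The most recent record strictly more than ``chronicity_days`` before index.

    Shared by both rule engines: chronicity is decided by the least-stale
    evidence beyond the 90-day horizon.
    """
    older = [r for r in timeline.labs
             if (index_date - r.collected_at).days > config.chronicity_days]
    if not older:
        return None
    return _nearest_before(older)


def assess_ckd(timeline: PatientTimeline, index_date: date,
               config: AlgorithmConfig) -> CKDAssessment:
    """CKD chronicity rule at an abnormal-eGFR index date.

    The caller guarantees the index-date eGFR is abnormal; this function
    examines records more than 90 days older, converts the most recent one to
    eGFR, and calls CKD iff that evidence is itself below the threshold. No
    prior evidence means CKD cannot be established (negative).
    """
    demo = timeline.demographics
    evidence = beyond_window_evidence(timeline, index_date, config)
    if evidence is None:
        return CKDAssessment(positive=False, index_date=index_date, evidence_date=None,
                             rationale=CKDRationale.NO_PRIOR_RECORDS)
    egfr = _egfr_value(evidence.scr, demo.age_years, demo.sex, config.race_coefficient)
    if is_abnormal_egfr(egfr, config):
        return CKDAssessment(positive=True, index_date=index_date,
                             evidence_date=evidence.collected_at,
                             rationale=CKDRationale.PRIOR_LOW_EGFR_BEYOND_90D)
    return CKDAssessment(positive=False, index_date=index_date,
                         evidence_date=evidence.collected_at,
                         rationale=CKDRationale.PRIOR_NORMAL_EGFR_BEYOND_90D)


def first_abnormal_egfr_date(timeline: PatientTimeline, episode: HospitalEpisode,
                             config: AlgorithmConfig) -> Optional[date]:
    """Earliest in-episode date whose creatinine converts to an abnormal eGFR."""
    demo = timeline.demographics
    for r in timeline.labs:
        if episode.contains(r.collected_at):
            egfr = _egfr_value(r.scr, demo.age_years, demo.sex, config.race_coefficient)
            if is_abnormal_egfr(egfr, config):
                return r.collected_at
    return None


def diagnose_hospitalization(timeline: PatientTimeline, episode: HospitalEpisode,
                             config: AlgorithmConfig) -> HospitalizationDiagnosis:
    """Compose index selection, baseline selection and both rules.

    AKI and CKD verdicts are independent: AKI anchors on the highest abnormal
    creatinine, CKD on the first abnormal-eGFR date of the episode.
    """
    aki: Optional[AKIAssessment] = None
    if not (config.exclude_dialysis and timeline.demographics.on_dialysis):
        found = find_index_scr(timeline, episode, config)
        if found is not None:
            index_date, index_scr = found
            baseline = select_baseline(timeline, index_date, config)
            aki = assess_aki(index_date, index_scr, baseline, config)

    ckd: Optional[CKDAssessment] = None
    ckd_index = first_abnormal_egfr_date(timeline, episode, config)
    if ckd_index is not None:
        ckd = assess_ckd(timeline, ckd_index, config)

    return HospitalizationDiagnosis(patient_id=timeline.patient_id, episode=episode,
                                    aki=aki, ckd=ckd)


def diagnose_cohort(timelines: Sequence[PatientTimeline],
                    config: AlgorithmConfig) -> list[HospitalizationDiagnosis]:
    """One diagnosis per (patient, hospitalization), in cohort order."""
    out: list[HospitalizationDiagnosis] = []
    for tl in timelines:
        for ep in tl.episodes:
            out.append(diagnose_hospitalization(tl, ep, config))
    return out


def diagnoses_to_frame(diagnoses: Sequence[HospitalizationDiagnosis]):
    """Diagnoses as a flat table (absent assessments become negative calls)."""
    import pandas as pd

    rows = []
    for d in diagnoses:
        a, c = d.aki, d.ckd
        rows.append({
            "patient_id": d.patient_id,
            "admit_date": d.episode.admit_date.isoformat(),
            "aki": int(a.positive) if a else 0,
            "ckd": int(c.positive) if c else 0,
            "aki_rationale": a.rationale.value if a else "NOT_ASSESSED",
            "ckd_rationale": c.rationale.value if c else "NOT_ASSESSED",
            "index_date": a.index_date.isoformat() if a else "",
            "index_scr": a.index_scr if a else "",
            "baseline_value": "" if (a is None or a.baseline.assumed_normal)
                              else a.baseline.value,
            "baseline_window": a.baseline.window.value if a else "",
            "ckd_index_date": c.index_date.isoformat() if c else "",
            "ckd_evidence_date": (c.evidence_date.isoformat()
                                  if c and c.evidence_date else ""),
        })
    columns = ["patient_id", "admit_date", "aki", "ckd", "aki_rationale",
               "ckd_rationale", "index_date", "index_scr", "baseline_value",
               "baseline_window", "ckd_index_date", "ckd_evidence_date"]
    return pd.DataFrame(rows, columns=columns)
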