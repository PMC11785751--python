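"""The gold-standard (researcher) rule set.

Experienced reviewers do not anchor on a single index value: they scan *every*
abnormal in-episode creatinine and compare it against the patient's
pre-admission baseline — the nearest pre-admission record within the 7-day
acute window of the scanned value, else the nearest pre-admission record at
any distance, else an assumed-normal baseline. A hospitalization with one or
more firing scans is "a hospitalization with AKI event".

This deliberately differs from the computerized algorithm, which anchors on
the in-episode maximum and may take elevated in-episode values as baseline
when testing is dense — the documented false-negative mechanism. Both engines
share one :class:`~nephrodx.config.AlgorithmConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Optional, Sequence

from .cohort import HospitalEpisode, LabRecord, PatientTimeline
from .config import AlgorithmConfig
from .algorithm import beyond_window_evidence, first_abnormal_egfr_date
from .egfr import _egfr_value, is_abnormal_egfr


@dataclass(frozen=True)
class ReferenceDiagnosis:
    patient_id: str
    episode: HospitalEpisode
    aki: bool
    ckd: bool
    first_aki_event_date: Optional[date]

    def __post_init__(self) -> None:
        if self.aki != (self.first_aki_event_date is not None):
            raise ValueError("first_aki_event_date must be present iff aki is true")


def _nearest(records: Sequence[LabRecord]) -> LabRecord:
    latest = max(r.collected_at for r in records)
    same_day = [r for r in records if r.collected_at == latest]
    return min(same_day, key=lambda r: r.scr)


def adjudicate_aki(timeline: PatientTimeline, episode: HospitalEpisode,
                   config: AlgorithmConfig) -> tuple[bool, Optional[date]]:
    """Scan every abnormal in-episode creatinine against pre-admission baselines.

    Returns ``(fired, earliest_firing_date)``.
    """
    pre_admission = [r for r in timeline.labs if r.collected_at < episode.admit_date]
    in_episode = [r for r in timeline.labs
                  if episode.contains(r.collected_at)
                  and r.scr > config.scr_abnormal_threshold]
    for rec in in_episode:  # labs are date-sorted, so the first hit is earliest
        recent = [p for p in pre_admission
                  if 1 <= (rec.collected_at - p.collected_at).days <= config.acute_window_days]
        pool = recent or pre_admission
        if not pool:
            return True, rec.collected_at  # no prior records: assumed normal
        baseline = _nearest(pool).scr
        ratio = rec.scr / baseline
        fired = ratio > config.aki_ratio_threshold if config.ratio_strict \
            else ratio >= config.aki_ratio_threshold
        if fired:
            return True, rec.collected_at
    return False, None


def adjudicate_ckd(timeline: PatientTimeline, index_date: date,
                   config: AlgorithmConfig) -> bool:
    """CKD chronicity by the most recent eGFR evidence beyond the 90-day horizon.

    With no prior records the baseline eGFR is assumed normal (no CKD).
    """
    evidence = beyond_window_evidence(timeline, index_date, config)
    if evidence is None:
        return False
    demo = timeline.demographics
    egfr = _egfr_value(evidence.scr, demo.age_years, demo.sex, config.race_coefficient)
    return is_abnormal_egfr(egfr, config)


def adjudicate_hospitalization(timeline: PatientTimeline, episode: HospitalEpisode,
                               config: AlgorithmConfig) -> ReferenceDiagnosis:
    aki, first_date = adjudicate_aki(timeline, episode, config)
    ckd_index = first_abnormal_egfr_date(timeline, episode, config)
    ckd = adjudicate_ckd(timeline, ckd_index, config) if ckd_index is not None else False
    return ReferenceDiagnosis(patient_id=timeline.patient_id, episode=episode,
                              aki=aki, ckd=ckd, first_aki_event_date=first_date)


def adjudicate_cohort(timelines: Sequence[PatientTimeline],
                      config: AlgorithmConfig) -> list[ReferenceDiagnosis]:
    out: list[ReferenceDiagnosis] = []
    for tl in timelines:
        for ep in tl.episodes:
            out.append(adjudicate_hospitalization(tl, ep, config))
    return out


def references_to_frame(diagnoses: Sequence[ReferenceDiagnosis]):
    """Reference diagnoses as a flat table, column-compatible with the
    computerized algorithm's output for joining."""
    import pandas as pd

    rows = [{
        "patient_id": d.patient_id,
        "admit_date": d.episode.admit_date.isoformat(),
        "aki": int(d.aki),
        "ckd": int(d.ckd),
        "first_aki_event_date": (d.first_aki_event_date.isoformat()
                                 if d.first_aki_event_date else ""),
    } for d in diagnoses]
    return pd.DataFrame(rows, columns=["patient_id", "admit_date", "aki", "ckd",
                                       "first_aki_event_date"])
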