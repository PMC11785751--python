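from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest

from nephrodx import AlgorithmConfig, Demographics, HospitalEpisode, LabRecord, PatientTimeline

BASE = date(2020, 6, 1)


def day(offset: int) -> date:
    """Calendar date at a whole-day offset from the reference admission day."""
    return BASE + timedelta(days=offset)


def make_timeline(labs, *, episode=(0, 10), sex="male", age=70.0, dialysis=False,
                  pid="P1", clinician_dx=None) -> PatientTimeline:
    """Timeline from (day-offset, scr) pairs; offsets are relative to admission."""
    demo = Demographics(patient_id=pid, sex=sex, age_years=age, on_dialysis=dialysis)
    records = [LabRecord(collected_at=day(off), scr=scr, patient_id=pid)
               for off, scr in labs]
    ep = HospitalEpisode(patient_id=pid, admit_date=day(episode[0]),
                         discharge_date=day(episode[1]))
    return PatientTimeline(demographics=demo, labs=records, episodes=[ep],
                           clinician_dx=clinician_dx)


def random_timeline(rng: np.random.Generator) -> PatientTimeline:
    """A small random patient: arbitrary offsets/values around one episode."""
    n = int(rng.integers(1, 12))
    offsets = rng.integers(-200, 15, size=n)
    labs = [(int(o), float(rng.uniform(0.4, 6.0))) for o in offsets]
    length = int(rng.integers(1, 15))
    sex = "male" if rng.random() < 0.5 else "female"
    age = float(rng.uniform(21, 95))
    return make_timeline(labs, episode=(0, length), sex=sex, age=age)


@pytest.fixture
def cfg() -> AlgorithmConfig:
    return AlgorithmConfig()
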