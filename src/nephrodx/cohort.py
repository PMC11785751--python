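"""Domain types for patients, labs and hospitalizations, plus CSV ingestion.

The in-memory unit is the :class:`PatientTimeline`: demographics, a date-sorted
creatinine series, hospitalization episodes, and (optionally) the clinician's
discharge diagnoses. Dates are day-granular — the study's rules operate on
calendar days, and multiple same-day tests are all retained.

CSV layout (override any column name through a schema mapping):

=================  =========================================================
file               default columns
=================  =========================================================
labs               patient_id, date (ISO-8601), scr_mg_dl
demographics       patient_id, sex, age, dialysis, source
episodes           patient_id, admit_date, discharge_date
clinician          patient_id, clin_aki, clin_ckd
=================  =========================================================
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import CohortValidationError, SchemaError

logger = logging.getLogger(__name__)

SEXES = ("male", "female")
SOURCES = ("ED", "OPD", "unknown")

DEFAULT_SCHEMA: dict[str, dict[str, str]] = {
    "labs": {"patient_id": "patient_id", "date": "date", "scr": "scr_mg_dl"},
    "demographics": {"patient_id": "patient_id", "sex": "sex", "age": "age",
                     "dialysis": "dialysis", "source": "source"},
    "episodes": {"patient_id": "patient_id", "admit_date": "admit_date",
                 "discharge_date": "discharge_date"},
    "clinician": {"patient_id": "patient_id", "aki": "clin_aki", "ckd": "clin_ckd"},
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class LabRecord:
    """One dated serum-creatinine measurement (mg/dL) for one patient."""

    collected_at: date
    scr: float
    patient_id: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if not (isinstance(self.collected_at, date) and not isinstance(self.collected_at, bool)):
            raise ValueError("collected_at must be a datetime.date")
        if not (math.isfinite(self.scr) and self.scr > 0):
            raise ValueError(f"scr must be positive and finite, got {self.scr!r}")


@dataclass(frozen=True)
class Demographics:
    patient_id: str
    sex: str
    age_years: float
    on_dialysis: bool = False
    source: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not (0 <= self.age_years <= 130):
            raise ValueError(f"age_years must lie in [0, 130], got {self.age_years!r}")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")


@dataclass(frozen=True)
class HospitalEpisode:
    patient_id: str
    admit_date: date
    discharge_date: date

    def __post_init__(self) -> None:
        if self.admit_date > self.discharge_date:
            raise ValueError("admit_date must not be after discharge_date")

    def contains(self, day: date) -> bool:
        return self.admit_date <= day <= self.discharge_date


@dataclass
class PatientTimeline:
    """Demographics plus the full dated creatinine series for one patient.

    Labs are sorted ascending by (date, value) on construction, so diagnoses
    are invariant under any permutation or duplication of the input records.
    """

    demographics: Demographics
    labs: list[LabRecord]
    episodes: list[HospitalEpisode] = field(default_factory=list)
    clinician_dx: Optional[tuple[bool, bool]] = None  # (aki, ckd)

    def __post_init__(self) -> None:
        pid = self.demographics.patient_id
        for rec in self.labs:
            if rec.patient_id and rec.patient_id != pid:
                raise ValueError(f"lab record patient_id {rec.patient_id!r} != {pid!r}")
        for ep in self.episodes:
            if ep.patient_id != pid:
                raise ValueError(f"episode patient_id {ep.patient_id!r} != {pid!r}")
        self.labs = sorted(self.labs, key=lambda r: (r.collected_at, r.scr))
        self.episodes = sorted(self.episodes, key=lambda e: e.admit_date)

    @property
    def patient_id(self) -> str:
        return self.demographics.patient_id

    def records_on_or_before(self, day: date) -> list[LabRecord]:
        return [r for r in self.labs if r.collected_at <= day]


# ---------------------------------------------------------------------------
# Windowed retrieval
# ---------------------------------------------------------------------------

def window_records(timeline: PatientTimeline, index_date: date,
                   start_days_before: int, end_days_before: int) -> list[LabRecord]:
    """Records collected between ``end_days_before`` and ``start_days_before``
    whole days before ``index_date``, both endpoints inclusive.

    The index day itself (offset 0) is never part of a lookback window, hence
    both bounds must be at least 1. Order of the underlying series is preserved.
    """
    if start_days_before > end_days_before:
        raise ValueError("start_days_before must not exceed end_days_before")
    if start_days_before < 1:
        raise ValueError("lookback windows start at least 1 day before the index day")
    lo = index_date - timedelta(days=end_days_before)
    hi = index_date - timedelta(days=start_days_before)
    return [r for r in timeline.labs if lo <= r.collected_at <= hi]


# ---------------------------------------------------------------------------
# CSV ingestion
# ---------------------------------------------------------------------------

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", ""}


def _parse_bool(value, *, default: Optional[bool] = None) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        if default is None:
            raise ValueError("missing boolean value")
        return default
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        if s == "" and default is not None:
            return default
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def _parse_date(value) -> date:
    if isinstance(value, date):
        return value
    ts = pd.Timestamp(str(value))
    return ts.date()


def _require_columns(df: pd.DataFrame, cols: Mapping[str, str], what: str) -> None:
    missing = [actual for actual in cols.values() if actual not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {missing}")


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _merged_schema(schema: Optional[Mapping[str, Mapping[str, str]]]) -> dict[str, dict[str, str]]:
    merged = {k: dict(v) for k, v in DEFAULT_SCHEMA.items()}
    for table, cols in (schema or {}).items():
        if table not in merged:
            raise SchemaError(f"unknown table {table!r} in schema mapping")
        merged[table].update(cols)
    return merged


def load_cohort(labs_path, demographics_path, episodes_path, clinician_path=None,
                schema: Optional[Mapping[str, Mapping[str, str]]] = None,
                ) -> list[PatientTimeline]:
    """Read the cohort CSVs and assemble one :class:`PatientTimeline` per patient.

    Every parseable lab row lands in exactly one timeline (row-count
    conservation); rows violating a field invariant are collected and reported
    together in a :class:`CohortValidationError` with their 1-based row numbers.
    Patients appearing in the labs file without a demographics row are a schema
    error (sex and age are required by the eGFR equation).
    """
    sch = _merged_schema(schema)

    demo_df = _read_csv(demographics_path)
    if demo_df.empty:
        logger.warning("demographics file %s is empty; cohort is empty", demographics_path)
        return []
    _require_columns(demo_df, sch["demographics"], "demographics")

    labs_df = _read_csv(labs_path)
    if labs_df.empty:
        logger.warning("labs file %s is empty", labs_path)
    else:
        _require_columns(labs_df, sch["labs"], "labs")

    epi_df = _read_csv(episodes_path)
    if not epi_df.empty:
        _require_columns(epi_df, sch["episodes"], "episodes")

    clin_df = pd.DataFrame()
    if clinician_path is not None:
        clin_df = _read_csv(clinician_path)
        if not clin_df.empty:
            _require_columns(clin_df, sch["clinician"], "clinician")

    errors: list[tuple[int, str]] = []

    demographics: dict[str, Demographics] = {}
    c = sch["demographics"]
    for i, row in enumerate(demo_df.itertuples(index=False), start=1):
        row = row._asdict()
        pid = str(row[c["patient_id"]])
        try:
            demographics[pid] = Demographics(
                patient_id=pid,
                sex=str(row[c["sex"]]).strip().lower(),
                age_years=float(row[c["age"]]),
                on_dialysis=_parse_bool(row.get(c["dialysis"], ""), default=False),
                source=str(row.get(c["source"], "unknown")).strip() or "unknown",
            )
        except (ValueError, KeyError) as exc:
            errors.append((i, f"demographics: {exc}"))

    labs: dict[str, list[LabRecord]] = {pid: [] for pid in demographics}
    c = sch["labs"]
    if not labs_df.empty:
        for i, row in enumerate(labs_df.itertuples(index=False), start=1):
            row = row._asdict()
            pid = str(row[c["patient_id"]])
            try:
                scr = float(row[c["scr"]])
                rec = LabRecord(collected_at=_parse_date(row[c["date"]]), scr=scr,
                                patient_id=pid)
            except (ValueError, TypeError) as exc:
                errors.append((i, f"labs: {exc}"))
                continue
            if pid not in labs:
                errors.append((i, f"labs: patient {pid!r} has no demographics row"))
                continue
            labs[pid].append(rec)

    episodes: dict[str, list[HospitalEpisode]] = {pid: [] for pid in demographics}
    c = sch["episodes"]
    if not epi_df.empty:
        for i, row in enumerate(epi_df.itertuples(index=False), start=1):
            row = row._asdict()
            pid = str(row[c["patient_id"]])
            try:
                ep = HospitalEpisode(patient_id=pid,
                                     admit_date=_parse_date(row[c["admit_date"]]),
                                     discharge_date=_parse_date(row[c["discharge_date"]]))
            except (ValueError, TypeError) as exc:
                errors.append((i, f"episodes: {exc}"))
                continue
            if pid not in episodes:
                errors.append((i, f"episodes: patient {pid!r} has no demographics row"))
                continue
            episodes[pid].append(ep)

    clinician: dict[str, tuple[bool, bool]] = {}
    c = sch["clinician"]
    if not clin_df.empty:
        for i, row in enumerate(clin_df.itertuples(index=False), start=1):
            row = row._asdict()
            pid = str(row[c["patient_id"]])
            try:
                clinician[pid] = (_parse_bool(row[c["aki"]]), _parse_bool(row[c["ckd"]]))
            except (ValueError, KeyError) as exc:
                errors.append((i, f"clinician: {exc}"))

    if errors:
        raise CohortValidationError(errors)

    return [
        PatientTimeline(demographics=demo, labs=labs[pid], episodes=episodes[pid],
                        clinician_dx=clinician.get(pid))
        for pid, demo in demographics.items()
    ]


# ---------------------------------------------------------------------------
# Serialization (round-trips load_cohort)
# ---------------------------------------------------------------------------

def cohort_frames(timelines: Sequence[PatientTimeline]) -> dict[str, pd.DataFrame]:
    """The cohort as four DataFrames in the default CSV dialect."""
    labs, demo, epis, clin = [], [], [], []
    for tl in timelines:
        d = tl.demographics
        demo.append({"patient_id": d.patient_id, "sex": d.sex, "age": d.age_years,
                     "dialysis": int(d.on_dialysis), "source": d.source})
        for r in tl.labs:
            labs.append({"patient_id": tl.patient_id,
                         "date": r.collected_at.isoformat(), "scr_mg_dl": r.scr})
        for e in tl.episodes:
            epis.append({"patient_id": tl.patient_id,
                         "admit_date": e.admit_date.isoformat(),
                         "discharge_date": e.discharge_date.isoformat()})
        if tl.clinician_dx is not None:
            clin.append({"patient_id": tl.patient_id,
                         "clin_aki": int(tl.clinician_dx[0]),
                         "clin_ckd": int(tl.clinician_dx[1])})
    return {
        "labs": pd.DataFrame(labs, columns=["patient_id", "date", "scr_mg_dl"]),
        "demographics": pd.DataFrame(
            demo, columns=["patient_id", "sex", "age", "dialysis", "source"]),
        "episodes": pd.DataFrame(
            epis, columns=["patient_id", "admit_date", "discharge_date"]),
        "clinician": pd.DataFrame(clin, columns=["patient_id", "clin_aki", "clin_ckd"]),
    }


def write_cohort(timelines: Sequence[PatientTimeline], out_dir) -> dict[str, Path]:
    """Write labs/demographics/episodes(/clinician) CSVs; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = cohort_frames(timelines)
    paths = {}
    for name, df in frames.items():
        if name == "clinician" and df.empty:
            continue
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


def load_cohort_dir(cohort_dir, schema=None) -> list[PatientTimeline]:
    """Convenience wrapper: load a directory written by :func:`write_cohort`."""
    d = Path(cohort_dir)
    clin = d / "clinician.csv"
    return load_cohort(d / "labs.csv", d / "demographics.csv", d / "episodes.csv",
                       clinician_path=clin if clin.exists() else None, schema=schema)
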