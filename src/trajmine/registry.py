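"""Registry data substrate: patients, diagnosis events, readers and writers.

A :class:`Registry` pairs a patient table (id, sex, birth date, optional
death date) with a longitudinal event table (one row per patient, date,
level-3 ICD-10 code and discharge type).  Both live as pandas DataFrames;
the row-level dataclasses :class:`PatientRecord` and
:class:`DiagnosisEvent` exist for constructing and validating single
records in tests and small examples.

All dates are calendar days (no time of day).  The ``week`` covariate is
the ISO-8601 week of the event date and is always recomputable from it.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .icd10 import (
    DEATH_CODE,
    DEFAULT_EXCLUDED_CHAPTERS,
    KNOWN_CHAPTERS,
    chapter_of,
    is_level3,
)

logger = logging.getLogger("trajmine")

SEXES = ("male", "female")
DISCHARGE_TYPES = ("inpatient", "outpatient", "emergency")

PATIENT_COLUMNS = ["patient_id", "sex", "birth_date", "death_date"]
EVENT_COLUMNS = ["patient_id", "date", "code", "discharge_type"]


class RegistryError(ValueError):
    """A registry or registry file violates a structural invariant."""


def days_since_epoch(values) -> np.ndarray:
    """Datetime array -> float days since the Unix epoch, NaT -> NaN."""
    arr = np.asarray(values, dtype="datetime64[ns]")
    out = arr.astype("float64") / 86_400e9
    out[np.isnat(arr)] = np.nan
    return out


def iso_week(dates: pd.Series) -> pd.Series:
    """ISO-8601 week number (1-53) for a datetime series."""
    return dates.dt.isocalendar().week.astype("int64").reset_index(drop=True)


def whole_year_age(birth: pd.Series, at: pd.Series) -> pd.Series:
    """Completed calendar years between *birth* and *at* (floor)."""
    years = at.dt.year - birth.dt.year
    not_yet = (at.dt.month * 100 + at.dt.day) < (birth.dt.month * 100 + birth.dt.day)
    return (years - not_yet.astype(int)).astype("int64")


@dataclass(frozen=True)
class PatientRecord:
    """Demographic and vital-status anchor for one patient."""

    patient_id: str
    sex: str
    birth_date: dt.date
    death_date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise RegistryError(f"unknown sex {self.sex!r} for patient {self.patient_id}")
        if self.death_date is not None and self.death_date < self.birth_date:
            raise RegistryError(
                f"patient {self.patient_id}: death {self.death_date} precedes birth"
            )


@dataclass(frozen=True)
class DiagnosisEvent:
    """One time-stamped level-3 diagnosis assignment."""

    patient_id: str
    code: str
    date: dt.date
    discharge_type: str
    week: int | None = None

    def __post_init__(self) -> None:
        if not (is_level3(self.code) or self.code == DEATH_CODE):
            raise RegistryError(f"not a level-3 code: {self.code!r}")
        if self.discharge_type not in DISCHARGE_TYPES:
            raise RegistryError(f"unknown discharge type {self.discharge_type!r}")
        if self.week is None:
            object.__setattr__(self, "week", dt.date.isocalendar(self.date)[1])


@dataclass
class Registry:
    """Patient table + event table + observation window.

    ``patients`` columns: patient_id, sex, birth_date, death_date (NaT if
    alive).  ``events`` columns: patient_id, date, code, discharge_type,
    week.  Events are kept sorted by (patient_id, date, code) so that all
    derived quantities are deterministic.
    """

    patients: pd.DataFrame
    events: pd.DataFrame
    observation_window: tuple[pd.Timestamp, pd.Timestamp] | None = None

    def __post_init__(self) -> None:
        pats = self.patients.copy()
        evts = self.events.copy()
        missing = [c for c in PATIENT_COLUMNS if c not in pats.columns]
        if missing:
            raise RegistryError(f"patient table lacks columns {missing}")
        missing = [c for c in EVENT_COLUMNS if c not in evts.columns]
        if missing:
            raise RegistryError(f"event table lacks columns {missing}")
        pats["patient_id"] = pats["patient_id"].astype(str)
        pats["birth_date"] = pd.to_datetime(pats["birth_date"])
        pats["death_date"] = pd.to_datetime(pats["death_date"], errors="coerce")
        evts["patient_id"] = evts["patient_id"].astype(str)
        evts["date"] = pd.to_datetime(evts["date"])
        evts = evts.sort_values(
            ["patient_id", "date", "code", "discharge_type"], kind="mergesort"
        ).reset_index(drop=True)
        evts["week"] = iso_week(evts["date"])
        self.patients = pats.reset_index(drop=True)
        self.events = evts[EVENT_COLUMNS + ["week"]]
        if self.observation_window is None and len(evts):
            self.observation_window = (evts["date"].min(), evts["date"].max())
        elif self.observation_window is not None:
            lo, hi = self.observation_window
            self.observation_window = (pd.Timestamp(lo), pd.Timestamp(hi))

    # -- basic accessors -------------------------------------------------
    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def codes(self) -> list[str]:
        return sorted(self.events["code"].unique())

    def first_occurrences(self) -> pd.DataFrame:
        """Patients x codes table of first-occurrence dates (NaT = never).

        The first occurrence of a code for a patient is the minimum event
        date; it is the anchor for every temporal statistic downstream.
        """
        if self.events.empty:
            return pd.DataFrame(index=self.patients["patient_id"])
        table = (
            self.events.groupby(["patient_id", "code"], sort=True)["date"]
            .min()
            .unstack()
        )
        return table.reindex(self.patients["patient_id"])

    def validate(self) -> None:
        """Raise :class:`RegistryError` on any violated invariant."""
        problems: list[str] = []
        pats = self.patients
        dup = pats["patient_id"][pats["patient_id"].duplicated()]
        if len(dup):
            problems.append(f"duplicate patient ids: {sorted(set(dup))[:5]}")
        dead = pats["death_date"].notna()
        bad = pats.loc[dead & (pats["death_date"] < pats["birth_date"]), "patient_id"]
        if len(bad):
            problems.append(f"death before birth for patients {list(bad)[:5]}")
        evts = self.events
        unknown = set(evts["patient_id"]) - set(pats["patient_id"])
        if unknown:
            problems.append(f"events reference unknown patients {sorted(unknown)[:5]}")
        bad_codes = [
            c for c in evts["code"].unique() if not (is_level3(c) or c == DEATH_CODE)
        ]
        if bad_codes:
            problems.append(f"malformed codes {bad_codes[:5]}")
        merged = evts.merge(pats, on="patient_id", how="left")
        early = merged["date"] < merged["birth_date"]
        if early.any():
            problems.append(f"{int(early.sum())} events before patient birth")
        has_death = merged["death_date"].notna()
        late = has_death & (merged["date"] > merged["death_date"])
        if late.any():
            problems.append(f"{int(late.sum())} events after patient death")
        if self.observation_window is not None and len(evts):
            lo, hi = self.observation_window
            outside = (evts["date"] < lo) | (evts["date"] > hi)
            if outside.any():
                problems.append(
                    f"{int(outside.sum())} events outside the observation window"
                )
        if problems:
            raise RegistryError("; ".join(problems))

    def restrict_sex(self, sex: str) -> "Registry":
        """Sub-registry of one sex ('all' returns self unchanged)."""
        if sex == "all":
            return self
        if sex not in SEXES:
            raise RegistryError(f"unknown sex filter {sex!r}")
        pats = self.patients[self.patients["sex"] == sex]
        keep = set(pats["patient_id"])
        evts = self.events[self.events["patient_id"].isin(keep)]
        return Registry(pats, evts, self.observation_window)

    def equals(self, other: "Registry") -> bool:
        return self.patients.equals(other.patients) and self.events.equals(other.events)


# ---------------------------------------------------------------------------
# Death-code injection and chapter filtering
# ---------------------------------------------------------------------------

def inject_death_events(registry: Registry, horizon_years: float = 5.0) -> Registry:
    """Append one Y99 event at each deceased patient's death date.

    The mortality horizon itself (death within *horizon_years* of a
    preceding first diagnosis, 5 years by default) is enforced by the
    pair-counting window downstream: a D1 -> Y99 pair only counts patients
    whose Y99 event falls within the analysis window after D1's first
    occurrence.  Living patients receive no event; registries without
    deaths pass through unchanged.  Idempotent: existing Y99 events are
    replaced, never duplicated.
    """
    if horizon_years <= 0:
        raise RegistryError("horizon_years must be positive")
    dead = registry.patients[registry.patients["death_date"].notna()]
    events = registry.events[registry.events["code"] != DEATH_CODE]
    if dead.empty:
        if len(events) == len(registry.events):
            return registry
        return Registry(registry.patients, events, registry.observation_window)
    deaths = pd.DataFrame(
        {
            "patient_id": dead["patient_id"].to_numpy(),
            "date": dead["death_date"].to_numpy(),
            "code": DEATH_CODE,
            # the terminal event is not a hospital discharge; the type is a
            # placeholder and Y99 events never enter matching pools
            "discharge_type": "inpatient",
        }
    )
    window = registry.observation_window
    if window is not None:
        lo, hi = window
        window = (min(lo, deaths["date"].min()), max(hi, deaths["date"].max()))
    merged = pd.concat([events, deaths], ignore_index=True)
    return Registry(registry.patients, merged, window)


def filter_chapters(
    events: pd.DataFrame,
    excluded_chapters: Iterable[str] = DEFAULT_EXCLUDED_CHAPTERS,
) -> pd.DataFrame:
    """Drop events whose code belongs to an excluded ICD-10 chapter.

    The death code Y99 is always retained even though its letter falls in
    the excluded external-causes chapter: mortality is a first-class
    outcome of the analysis.
    """
    excluded = set(excluded_chapters)
    unknown = excluded - KNOWN_CHAPTERS
    if unknown:
        raise RegistryError(f"unknown chapter labels {sorted(unknown)}")
    if not excluded:
        return events
    codes = events["code"].unique()
    drop = {
        c for c in codes if c != DEATH_CODE and chapter_of(c) in excluded
    }
    return events[~events["code"].isin(drop)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Delimited-text readers and writers
# ---------------------------------------------------------------------------

_WINDOW_TAG = "# observation_window="


def _parse_dates(frame: pd.DataFrame, column: str, path, allow_empty: bool = False):
    raw = frame[column]
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    empty = raw.isna() | (raw.astype(str).str.strip() == "")
    bad = parsed.isna() & ~empty
    if bad.any():
        rows = [int(i) + 2 for i in frame.index[bad][:5]]  # +2: header + 1-based
        raise RegistryError(f"{path}: unparseable {column} at rows {rows}")
    if not allow_empty and empty.any():
        rows = [int(i) + 2 for i in frame.index[empty][:5]]
        raise RegistryError(f"{path}: missing {column} at rows {rows}")
    return parsed


def read_registry(events_path, patients_path, sep: str = ",") -> Registry:
    """Read a registry from the two delimited text files.

    Events file columns: patient_id, date (ISO-8601), code, discharge_type.
    Patients file columns: patient_id, sex, birth_date, death_date (empty
    if alive).  Structural problems are rejected with the offending rows
    or identifiers named.
    """
    patients = pd.read_csv(patients_path, sep=sep, comment="#", dtype=str)
    missing = [c for c in PATIENT_COLUMNS if c not in patients.columns]
    if missing:
        raise RegistryError(f"{patients_path}: missing columns {missing}")
    patients["birth_date"] = _parse_dates(patients, "birth_date", patients_path)
    patients["death_date"] = _parse_dates(
        patients, "death_date", patients_path, allow_empty=True
    )
    bad_sex = ~patients["sex"].isin(SEXES)
    if bad_sex.any():
        rows = [int(i) + 2 for i in patients.index[bad_sex][:5]]
        raise RegistryError(f"{patients_path}: unknown sex at rows {rows}")

    events = pd.read_csv(events_path, sep=sep, comment="#", dtype=str)
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise RegistryError(f"{events_path}: missing columns {missing}")
    if len(events):
        events["date"] = _parse_dates(events, "date", events_path)
    else:
        events["date"] = pd.to_datetime(events["date"])
    orphans = set(events["patient_id"]) - set(patients["patient_id"])
    if orphans:
        raise RegistryError(
            f"{events_path}: events reference unknown patient ids "
            f"{sorted(orphans)[:5]}"
        )

    window = None
    with open(events_path) as handle:
        for line in handle:
            if line.startswith(_WINDOW_TAG):
                lo, hi = line[len(_WINDOW_TAG):].strip().split("..")
                window = (pd.Timestamp(lo), pd.Timestamp(hi))
            if not line.startswith("#"):
                break
    return Registry(patients, events, window)


def write_registry(registry: Registry, events_path, patients_path) -> None:
    """Write the two delimited registry files (round-trip stable)."""
    pats = registry.patients.copy()
    pats["birth_date"] = pats["birth_date"].dt.strftime("%Y-%m-%d")
    pats["death_date"] = pats["death_date"].dt.strftime("%Y-%m-%d").fillna("")
    pats[PATIENT_COLUMNS].to_csv(patients_path, index=False)

    evts = registry.events.copy()
    evts["date"] = evts["date"].dt.strftime("%Y-%m-%d")
    with open(events_path, "w") as handle:
        if registry.observation_window is not None:
            lo, hi = registry.observation_window
            handle.write(f"{_WINDOW_TAG}{lo.date()}..{hi.date()}\n")
        evts[EVENT_COLUMNS].to_csv(handle, index=False)


def registry_from_records(
    patients: Sequence[PatientRecord], events: Sequence[DiagnosisEvent]
) -> Registry:
    """Build a registry from row-level records (convenience for tests)."""
    pat_frame = pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "sex": p.sex,
                "birth_date": p.birth_date,
                "death_date": p.death_date,
            }
            for p in patients
        ],
        columns=PATIENT_COLUMNS,
    )
    evt_frame = pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "date": e.date,
                "code": e.code,
                "discharge_type": e.discharge_type,
            }
            for e in events
        ],
        columns=EVENT_COLUMNS,
    )
    registry = Registry(pat_frame, evt_frame)
    registry.validate()
    return registry
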