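"""Working data model: day records + participant covariates + day-level auxiliaries.

Tables are plain pandas DataFrames with fixed schemas; :class:`TrialDataset`
bundles them with validation and CSV round-tripping. Also houses the
photoperiod (daylength) computation used for the daylength auxiliary.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .accel import DAY_COLUMNS, STATUSES
from .errors import MalformedInputError, ParameterError, SchemaError

ARM_CODES = (1, 2, 3)  # 1=individual therapy, 2=group therapy, 3=usual care

PARTICIPANT_COLUMNS = ["participant_id", "arm", "female", "age", "region", "bmi"]
AUX_COLUMNS = [
    "participant_id",
    "year",
    "day_of_week",
    "date",
    "temperature",
    "sqrt_rainfall",
    "sunshine",
    "daylength",
]
AUX_VARS = ["temperature", "sqrt_rainfall", "sunshine", "daylength"]


@dataclass
class TrialDataset:
    """Day-level records joined with participant covariates and auxiliaries.

    ``days``: columns ``participant_id, year, week, day_of_week, step_count,
    wear_minutes, status`` (optionally ``substituted_from``).
    ``participants``: one row per participant with arm/sex/age/region/bmi.
    ``auxiliaries``: per participant-day weather variables (optional; an
    optional ``week`` column distinguishes measurement-week days from
    following-week days, defaulting to 1).
    ``age_center`` is the constant subtracted from ``age`` when building
    model designs; it is fixed at load time so predictions are reproducible.
    """

    days: pd.DataFrame
    participants: pd.DataFrame
    auxiliaries: Optional[pd.DataFrame] = None
    age_center: Optional[float] = None

    def __post_init__(self):
        if self.age_center is None and len(self.participants):
            self.age_center = float(self.participants["age"].mean())

    def validate(self) -> "TrialDataset":
        _validate_days(self.days)
        _validate_participants(self.participants)
        known = set(self.participants["participant_id"])
        unknown = set(self.days["participant_id"]) - known
        if unknown:
            raise SchemaError(f"day records reference unknown participants: {sorted(unknown)[:5]}")
        if self.auxiliaries is not None:
            _validate_aux(self.auxiliaries)
        return self

    def copy(self) -> "TrialDataset":
        return TrialDataset(
            days=self.days.copy(),
            participants=self.participants.copy(),
            auxiliaries=None if self.auxiliaries is None else self.auxiliaries.copy(),
            age_center=self.age_center,
        )

    @property
    def week1_days(self) -> pd.DataFrame:
        return self.days[self.days["week"] == 1]


def _require_columns(df: pd.DataFrame, required, table: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table missing required columns: {missing}")


def _validate_days(days: pd.DataFrame):
    _require_columns(days, DAY_COLUMNS, "days")
    bad_dow = days.loc[~days["day_of_week"].isin(range(1, 8)), "day_of_week"]
    if len(bad_dow):
        raise SchemaError(f"invalid day_of_week values: {sorted(bad_dow.unique().tolist())}")
    bad_status = days.loc[~days["status"].isin(STATUSES), "status"]
    if len(bad_status):
        raise SchemaError(f"invalid status values: {sorted(bad_status.unique().tolist())}")
    if (days["wear_minutes"] < 0).any() or (days["wear_minutes"] > 1440).any():
        raise SchemaError("wear_minutes must lie in [0, 1440]")
    if (days["step_count"] < 0).any():
        raise SchemaError("step_count must be non-negative")
    key = ["participant_id", "year", "week", "day_of_week"]
    dup = days.duplicated(subset=key)
    if dup.any():
        first = days.loc[dup, key].iloc[0].tolist()
        raise SchemaError(f"duplicate day records for cell {first}")


def _validate_participants(participants: pd.DataFrame):
    _require_columns(participants, PARTICIPANT_COLUMNS, "participants")
    bad_arm = participants.loc[~participants["arm"].isin(ARM_CODES), "arm"]
    if len(bad_arm):
        raise SchemaError(f"unknown arm codes: {sorted(bad_arm.unique().tolist())}")
    if participants["participant_id"].duplicated().any():
        raise SchemaError("duplicate participant_id rows in participants table")
    if not participants["female"].isin((0, 1)).all():
        raise SchemaError("female must be binary 0/1")


def _validate_aux(aux: pd.DataFrame):
    _require_columns(aux, AUX_COLUMNS, "auxiliaries")
    if (aux["sqrt_rainfall"] < 0).any():
        raise SchemaError("sqrt_rainfall must be non-negative")
    if ((aux["daylength"] <= 0) | (aux["daylength"] >= 24)).any():
        raise SchemaError("daylength must lie strictly inside (0, 24) hours")


def read_trial(days_path, participants_path, aux_path=None) -> TrialDataset:
    """Read a dataset from CSV files and validate it."""
    days = pd.read_csv(days_path)
    participants = pd.read_csv(participants_path)
    aux = pd.read_csv(aux_path) if aux_path is not None else None
    if "substituted_from" in days.columns:
        days["substituted_from"] = days["substituted_from"].astype("Int64")
    if aux is not None and "week" not in aux.columns:
        aux["week"] = 1
    ds = TrialDataset(days=days, participants=participants, auxiliaries=aux)
    return ds.validate()


def write_trial(dataset: TrialDataset, days_path, participants_path, aux_path=None):
    """Write a dataset back to CSV files (inverse of :func:`read_trial`)."""
    dataset.days.to_csv(days_path, index=False)
    dataset.participants.to_csv(participants_path, index=False)
    if aux_path is not None and dataset.auxiliaries is not None:
        dataset.auxiliaries.to_csv(aux_path, index=False)


# ---------------------------------------------------------------------------
# photoperiod


def compute_daylength(latitude: float, date, horizon: float = 0.8333) -> float:
    """Photoperiod in hours for ``latitude`` (degrees) on ``date``.

    Uses the solar-declination / hour-angle construction of Forsythe et al.
    (1995); ``horizon`` is the sun altitude (degrees below horizontal) defining
    sunrise/sunset, 0.8333 for the standard refraction-corrected definition.
    Latitudes poleward of the polar circles are rejected.
    """
    if abs(latitude) >= 66.5:
        raise ParameterError(f"latitude {latitude} is polar; only |lat| < 66.5 supported")
    doy = _day_of_year(date)
    theta = 0.2163108 + 2.0 * np.arctan(0.9671396 * np.tan(0.00860 * (doy - 186.0)))
    decl = np.arcsin(0.39795 * np.cos(theta))  # solar declination, radians
    lat = np.deg2rad(latitude)
    p = np.deg2rad(horizon)
    cos_h = (np.sin(p) + np.sin(lat) * np.sin(decl)) / (np.cos(lat) * np.cos(decl))
    cos_h = np.clip(cos_h, -1.0, 1.0)
    return float(24.0 - (24.0 / np.pi) * np.arccos(cos_h))


def _day_of_year(date) -> float:
    if isinstance(date, str):
        date = pd.Timestamp(date)
    if isinstance(date, pd.Timestamp):
        date = date.date()
    if isinstance(date, _dt.datetime):
        date = date.date()
    if isinstance(date, _dt.date):
        return float(date.timetuple().tm_yday)
    if isinstance(date, (int, float, np.integer, np.floating)):
        return float(date)  # already a day-of-year
    raise MalformedInputError(f"cannot interpret date {date!r}")
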