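"""Epoch-level step streams: non-wear detection, day aggregation, classification.

A day of accelerometer output is a sequence of short epochs (typically 5 s)
each carrying a step count. Long runs of zero-step epochs are treated as
non-wear; wear time is the worn-epoch total, and each day is classified as
observed / partial / missing by comparing wear time against a cut-off.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import MalformedInputError, ParameterError, SchemaError

SECONDS_PER_DAY = 86400
DEFAULT_EPOCH_LEN = 5
DEFAULT_RUN_MINUTES = 60.0
DEFAULT_CUTOFF_MINUTES = 540.0

STATUS_OBSERVED = "observed"
STATUS_PARTIAL = "partial"
STATUS_MISSING = "missing"
STATUSES = (STATUS_OBSERVED, STATUS_PARTIAL, STATUS_MISSING)

DAY_COLUMNS = [
    "participant_id",
    "year",
    "week",
    "day_of_week",
    "step_count",
    "wear_minutes",
    "status",
]

EPOCH_COLUMNS = [
    "participant_id",
    "year",
    "week",
    "day_of_week",
    "epoch_index",
    "steps",
]


@dataclass
class EpochStream:
    """One participant-day of raw epoch step counts.

    ``steps`` must cover exactly 24 h: ``len(steps) * epoch_len == 86400``.
    """

    participant_id: str
    year: int
    day_of_week: int
    steps: np.ndarray = field(repr=False)
    week: int = 1
    epoch_len: int = DEFAULT_EPOCH_LEN

    def __post_init__(self):
        self.steps = np.asarray(self.steps)
        if self.epoch_len <= 0 or int(self.epoch_len) != self.epoch_len:
            raise ParameterError(f"epoch_len must be a positive integer, got {self.epoch_len}")
        self.epoch_len = int(self.epoch_len)
        if self.steps.ndim != 1:
            raise MalformedInputError("steps must be a 1-d sequence")
        if self.steps.size * self.epoch_len != SECONDS_PER_DAY:
            raise MalformedInputError(
                f"stream does not cover 24 h: {self.steps.size} epochs of "
                f"{self.epoch_len} s = {self.steps.size * self.epoch_len} s, expected {SECONDS_PER_DAY}"
            )
        if np.any(self.steps < 0):
            raise MalformedInputError("step counts must be non-negative")
        if not 1 <= self.day_of_week <= 7:
            raise MalformedInputError(f"day_of_week must be in 1..7, got {self.day_of_week}")
        if self.week < 1:
            raise MalformedInputError(f"week must be >= 1, got {self.week}")


@dataclass
class DayRecord:
    """One (participant, year, day-of-week) cell at the day level."""

    participant_id: str
    year: int
    day_of_week: int
    week: int = 1
    step_count: int = 0
    wear_minutes: float = 0.0
    status: Optional[str] = None
    substituted_from: Optional[int] = None


def detect_nonwear(stream: EpochStream, run_minutes: float = DEFAULT_RUN_MINUTES) -> np.ndarray:
    """Return a boolean worn-mask for ``stream`` (True = worn).

    Every maximal run of consecutive zero-step epochs lasting at least
    ``run_minutes`` is flagged non-worn; all other epochs are worn.
    """
    if run_minutes <= 0:
        raise ParameterError(f"run_minutes must be positive, got {run_minutes}")
    run_epochs_f = run_minutes * 60.0 / stream.epoch_len
    run_epochs = int(round(run_epochs_f))
    if abs(run_epochs_f - run_epochs) > 1e-9 or run_epochs < 1:
        raise ParameterError(
            f"run_minutes={run_minutes} is not a positive multiple of the epoch length "
            f"({stream.epoch_len} s)"
        )
    zero = stream.steps == 0
    if not zero.any():
        return np.ones(stream.steps.size, dtype=bool)
    # run-length encode the zero indicator
    change = np.flatnonzero(np.diff(zero.astype(np.int8)))
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [zero.size]))
    mask = np.ones(zero.size, dtype=bool)
    for s, e in zip(starts, ends):
        if zero[s] and (e - s) >= run_epochs:
            mask[s:e] = False
    return mask


def summarize_day(stream: EpochStream, mask: np.ndarray) -> DayRecord:
    """Aggregate a masked stream to a :class:`DayRecord` (status unset)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stream.steps.shape:
        raise MalformedInputError(
            f"mask length {mask.size} does not match stream length {stream.steps.size}"
        )
    wear_minutes = float(mask.sum()) * stream.epoch_len / 60.0
    step_count = int(stream.steps[mask].sum())
    return DayRecord(
        participant_id=stream.participant_id,
        year=stream.year,
        day_of_week=stream.day_of_week,
        week=stream.week,
        step_count=step_count,
        wear_minutes=wear_minutes,
    )


def classify_day(record: DayRecord, cutoff_minutes: float = DEFAULT_CUTOFF_MINUTES) -> DayRecord:
    """Return a copy of ``record`` with its status set.

    wear 0 -> missing; 0 < wear < cutoff -> partial; wear >= cutoff -> observed.
    The boundary point (wear exactly at the cut-off) counts as observed.
    """
    if cutoff_minutes <= 0:
        raise ParameterError(f"cutoff_minutes must be positive, got {cutoff_minutes}")
    w = record.wear_minutes
    if w < 0:
        raise MalformedInputError(f"negative wear time: {w}")
    if w == 0:
        status = STATUS_MISSING
    elif w < cutoff_minutes:
        status = STATUS_PARTIAL
    else:
        status = STATUS_OBSERVED
    return replace(record, status=status)


def process_stream(
    stream: EpochStream,
    run_minutes: float = DEFAULT_RUN_MINUTES,
    cutoff_minutes: float = DEFAULT_CUTOFF_MINUTES,
) -> DayRecord:
    """detect_nonwear -> summarize_day -> classify_day for one stream."""
    mask = detect_nonwear(stream, run_minutes)
    rec = summarize_day(stream, mask)
    # a fully non-worn day carries no steps by definition
    if rec.wear_minutes == 0:
        rec.step_count = 0
    return classify_day(rec, cutoff_minutes)


def days_from_epochs(
    epochs: pd.DataFrame,
    epoch_len: int = DEFAULT_EPOCH_LEN,
    run_minutes: float = DEFAULT_RUN_MINUTES,
    cutoff_minutes: float = DEFAULT_CUTOFF_MINUTES,
) -> pd.DataFrame:
    """Convert a long epoch table to a classified day-level table.

    ``epochs`` needs columns participant_id, year, week, day_of_week,
    epoch_index, steps; a ``week`` column defaulting to 1 is added if absent.
    """
    epochs = epochs.copy()
    if "week" not in epochs.columns:
        epochs["week"] = 1
    missing = [c for c in EPOCH_COLUMNS if c not in epochs.columns]
    if missing:
        raise SchemaError(f"epoch table missing columns: {missing}")
    out = []
    keys = ["participant_id", "year", "week", "day_of_week"]
    for key, grp in epochs.groupby(keys, sort=True):
        grp = grp.sort_values("epoch_index")
        stream = EpochStream(
            participant_id=key[0],
            year=int(key[1]),
            week=int(key[2]),
            day_of_week=int(key[3]),
            steps=grp["steps"].to_numpy(),
            epoch_len=epoch_len,
        )
        rec = process_stream(stream, run_minutes, cutoff_minutes)
        out.append(
            {
                "participant_id": rec.participant_id,
                "year": rec.year,
                "week": rec.week,
                "day_of_week": rec.day_of_week,
                "step_count": rec.step_count,
                "wear_minutes": rec.wear_minutes,
                "status": rec.status,
            }
        )
    return pd.DataFrame(out, columns=DAY_COLUMNS)
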