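import numpy as np
import pandas as pd
import pytest

from stepmi.accel import STATUS_MISSING, STATUS_OBSERVED, STATUS_PARTIAL
from stepmi.trial_data import TrialDataset


def make_day(pid, year, dow, status, count=None, wear=None, week=1):
    if status == STATUS_OBSERVED:
        count = 8000 if count is None else count
        wear = 800.0 if wear is None else wear
    elif status == STATUS_PARTIAL:
        count = 3000 if count is None else count
        wear = 300.0 if wear is None else wear
    else:
        count, wear = 0, 0.0
    return {
        "participant_id": pid,
        "year": year,
        "week": week,
        "day_of_week": dow,
        "step_count": count,
        "wear_minutes": wear,
        "status": status,
    }


def make_participants(ids, arms=None):
    n = len(ids)
    arms = arms or [(i % 3) + 1 for i in range(n)]
    return pd.DataFrame(
        {
            "participant_id": ids,
            "arm": arms,
            "female": [i % 2 for i in range(n)],
            "age": [60.0 + i for i in range(n)],
            "region": [f"R{((i // 2) % 2) + 1}" for i in range(n)],
            "bmi": [28.0 + i for i in range(n)],
        }
    )


def full_grid_days(ids, status_fn=None, count=8000):
    """All 21 cells per participant; status_fn(pid, year, dow) -> status.
    ``count`` applies to observed cells; partial/missing keep their defaults."""
    rows = []
    for pid in ids:
        for year in (0, 1, 2):
            for dow in range(1, 8):
                status = status_fn(pid, year, dow) if status_fn else STATUS_OBSERVED
                c = count if status == STATUS_OBSERVED else None
                rows.append(make_day(pid, year, dow, status, count=c))
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_dataset():
    ids = [f"P{i}" for i in range(1, 7)]
    days = full_grid_days(ids)
    return TrialDataset(days=days, participants=make_participants(ids)).validate()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
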