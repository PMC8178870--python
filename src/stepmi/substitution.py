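"""Day-substitution: fill missing/partial measurement-week days from week 2.

Under the exchangeability-across-weeks assumption, a missing day in the
measurement week may be replaced by an observed (preferred) or partial
record for the same day of the week from the following week; a partial day
may only be upgraded to a week-2 observed record. Observed days are never
altered.
"""
from __future__ import annotations

import pandas as pd

from .accel import STATUS_MISSING, STATUS_OBSERVED, STATUS_PARTIAL
from .errors import MalformedInputError, ParameterError
from .trial_data import TrialDataset

_CELL = ["participant_id", "year", "day_of_week"]

STRATEGY_SAME_WEEKDAY = "same-weekday"
STRATEGY_SUNSHINE = "sunshine"


def day_substitute(dataset: TrialDataset, strategy: str = STRATEGY_SAME_WEEKDAY) -> TrialDataset:
    """Return a dataset whose days table has exactly the in-window cells,
    with eligible cells replaced by following-week records.

    Replacement rules: missing -> week-2 observed, else week-2 partial;
    partial -> week-2 observed only. ``substituted_from`` records the donor
    week on replaced cells.
    """
    if strategy not in (STRATEGY_SAME_WEEKDAY, STRATEGY_SUNSHINE):
        raise ParameterError(f"unknown substitution strategy: {strategy!r}")
    days = dataset.days
    week1 = days[days["week"] == 1].copy()
    if week1.duplicated(subset=_CELL).any():
        raise MalformedInputError("duplicate week-1 records for a (participant, year, day) cell")
    week2 = days[days["week"] == 2]
    if "substituted_from" not in week1.columns:
        week1["substituted_from"] = pd.array([pd.NA] * len(week1), dtype="Int64")
    else:
        week1["substituted_from"] = week1["substituted_from"].astype("Int64")
    if len(week2) == 0:
        out = dataset.copy()
        out.days = week1.reset_index(drop=True)
        return out
    if strategy == STRATEGY_SAME_WEEKDAY:
        week1 = _substitute_same_weekday(week1, week2)
    else:
        week1 = _substitute_sunshine(week1, week2, dataset)
    out = dataset.copy()
    out.days = week1.reset_index(drop=True)
    return out


def _pick_donor(cands: pd.DataFrame, allowed_statuses):
    """Best donor among week-2 candidates: observed preferred over partial."""
    for status in (STATUS_OBSERVED, STATUS_PARTIAL):
        if status not in allowed_statuses:
            continue
        hit = cands[cands["status"] == status]
        if len(hit):
            return hit.iloc[0]
    return None


def _apply_donor(week1, idx, donor):
    week1.loc[idx, "step_count"] = donor["step_count"]
    week1.loc[idx, "wear_minutes"] = donor["wear_minutes"]
    week1.loc[idx, "status"] = donor["status"]
    week1.loc[idx, "substituted_from"] = int(donor["week"])


def _substitute_same_weekday(week1: pd.DataFrame, week2: pd.DataFrame) -> pd.DataFrame:
    w2_groups = {k: g for k, g in week2.groupby(_CELL)}
    for idx, row in week1.iterrows():
        if row["status"] == STATUS_OBSERVED:
            continue
        cands = w2_groups.get((row["participant_id"], row["year"], row["day_of_week"]))
        if cands is None:
            continue
        allowed = (
            (STATUS_OBSERVED, STATUS_PARTIAL)
            if row["status"] == STATUS_MISSING
            else (STATUS_OBSERVED,)
        )
        donor = _pick_donor(cands, allowed)
        if donor is not None:
            _apply_donor(week1, idx, donor)
    return week1


def _substitute_sunshine(week1: pd.DataFrame, week2: pd.DataFrame, dataset: TrialDataset) -> pd.DataFrame:
    """Match donors on nearest sunshine hours rather than day of week.

    Ties break to the same day-of-week, then the earliest day. Each donor day
    is used at most once per (participant, year).
    """
    aux = dataset.auxiliaries
    if aux is None:
        raise ParameterError("sunshine strategy requires an auxiliaries table")
    if "week" not in aux.columns:
        aux = aux.assign(week=1)
    sun = aux.set_index(["participant_id", "year", "week", "day_of_week"])["sunshine"]
    for (pid, year), w2 in week2.groupby(["participant_id", "year"]):
        used = set()
        targets = week1[
            (week1["participant_id"] == pid)
            & (week1["year"] == year)
            & (week1["status"] != STATUS_OBSERVED)
        ]
        for idx, row in targets.sort_values("day_of_week").iterrows():
            try:
                target_sun = sun.loc[(pid, year, 1, row["day_of_week"])]
            except KeyError:
                continue
            allowed = (
                (STATUS_OBSERVED, STATUS_PARTIAL)
                if row["status"] == STATUS_MISSING
                else (STATUS_OBSERVED,)
            )
            best, best_key = None, None
            for j, cand in w2.iterrows():
                if j in used or cand["status"] not in allowed:
                    continue
                try:
                    cand_sun = sun.loc[(pid, year, 2, cand["day_of_week"])]
                except KeyError:
                    continue
                # prefer observed over partial, then sunshine distance, then
                # same weekday, then earliest day
                key = (
                    0 if cand["status"] == STATUS_OBSERVED else 1,
                    abs(cand_sun - target_sun),
                    0 if cand["day_of_week"] == row["day_of_week"] else 1,
                    cand["day_of_week"],
                )
                if best_key is None or key < best_key:
                    best, best_key = j, key
            if best is not None:
                _apply_donor(week1, idx, w2.loc[best])
                used.add(best)
    return week1


def substitution_report(before: TrialDataset, after: TrialDataset) -> pd.DataFrame:
    """Contingency of day statuses before x after substitution.

    Returns counts per (year, arm, day_of_week, status_before, status_after).
    """
    key = _CELL
    b = before.week1_days[key + ["status"]].rename(columns={"status": "status_before"})
    a = after.week1_days[key + ["status"]].rename(columns={"status": "status_after"})
    merged = b.merge(a, on=key, how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        raise MalformedInputError("before/after datasets do not cover the same cells")
    merged = merged.merge(before.participants[["participant_id", "arm"]], on="participant_id")
    out = (
        merged.groupby(["year", "arm", "day_of_week", "status_before", "status_after"])
        .size()
        .rename("n")
        .reset_index()
    )
    return out
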