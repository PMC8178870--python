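"""Delta-adjustment sensitivity analysis for MNAR assumptions.

After imputation under MAR, log step counts of cells that were missing or
partially observed are multiplied by a proportion delta <= 1, encoding the
belief that participants are less active when not wearing the device. On
the count scale this maps y to y**delta, so larger MAR counts are reduced
by more steps.
"""
from __future__ import annotations

from dataclasses import replace as _dc_replace
from typing import Iterable

import numpy as np

from .accel import STATUS_MISSING, STATUS_PARTIAL, STATUSES
from .errors import ParameterError
from .imputation import ImputedSet

DEFAULT_DELTA = 0.95
DEFAULT_TARGETS = (STATUS_MISSING, STATUS_PARTIAL)


def adjust_count(count, delta: float = DEFAULT_DELTA):
    """exp(delta * log(count)) == count ** delta, for counts > 0."""
    _check_delta(delta)
    count = np.asarray(count, dtype=float)
    out = np.where(count > 0, np.power(count, delta), count)
    return float(out) if out.ndim == 0 else out


def apply_delta(
    imputed: ImputedSet,
    delta: float = DEFAULT_DELTA,
    target_statuses: Iterable[str] = DEFAULT_TARGETS,
) -> ImputedSet:
    """Shrink log counts of originally missing/partial cells by ``delta``.

    The multiplication happens on the natural-log count scale (the stored
    log(count + offset) values are unwrapped first so that the adjustment is
    exactly exp(delta * log y)). Cells whose back-transformed count is zero
    are left unchanged. Bounds metadata is retained untouched; adjusted
    values may fall below a partial cell's lower bound, as the adjustment is
    applied after imputation by construction.
    """
    _check_delta(delta)
    targets = set(target_statuses)
    unknown = targets - set(STATUSES)
    if unknown:
        raise ParameterError(f"unknown target statuses: {sorted(unknown)}")

    data = imputed.data.copy()
    off = imputed.log_offset
    status = imputed.bounds.set_index(["participant_id", "year", "day_of_week"])["status"]
    keys = list(zip(data["participant_id"], data["year"], data["day_of_week"]))
    cell_status = status.loc[keys].to_numpy()
    hit = np.isin(cell_status, list(targets))

    s = data.loc[hit, "log_steps"].to_numpy(dtype=float)
    y = np.exp(s) - off
    pos = y > 0
    y_adj = np.where(pos, np.exp(delta * np.log(np.where(pos, y, 1.0))), y)
    data.loc[hit, "log_steps"] = np.log(np.maximum(y_adj, 0.0) + off)

    return ImputedSet(
        data=data,
        bounds=imputed.bounds,
        spec=_dc_replace(imputed.spec),
        diagnostics=imputed.diagnostics,
    )


def _check_delta(delta: float):
    if not (0.0 < delta <= 1.0):
        raise ParameterError(f"delta must lie in (0, 1], got {delta}")
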