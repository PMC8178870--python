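"""Synthetic three-arm step-count trial generator with known truth.

Structure mirrors a 3-arm trial (allocation 3:4:3) measured over 7
consecutive days at baseline, year 1 and year 2, with weekday effects,
weather-driven activity, configurable MCAR/MAR/MNAR wear mechanisms, an
optional extra week (for day-substitution testing) and optional epoch-level
streams. Arm effects are specified in steps/day and calibrated exactly on
the log scale, so the generating contrast is recoverable for acceptance
checks.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .accel import (
    DEFAULT_CUTOFF_MINUTES,
    EpochStream,
    STATUS_MISSING,
    STATUS_OBSERVED,
    STATUS_PARTIAL,
)
from .errors import ParameterError
from .trial_data import TrialDataset, compute_daylength

MINUTES_PER_DAY = 1440


@dataclass
class SimConfig:
    """Parameters of the synthetic trial generator (log-normal daily counts)."""

    n_participants: int = 300
    allocation: Tuple[int, int, int] = (3, 4, 3)
    seed: int = 0

    # latent activity (natural-log scale)
    baseline_log_mean: float = 8.55
    participant_sd: float = 0.45
    year_effects: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    weekday_effects: Tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0, -0.05, -0.15)
    sigma_day: float = 0.4
    baseline_week_sd: float = 0.2  # year-level deviation at baseline
    year_cov: Tuple[Tuple[float, float], Tuple[float, float]] = ((0.05, 0.02), (0.02, 0.05))
    arm_year_cov: Optional[Dict[int, np.ndarray]] = None  # per-arm override

    # arm effects in steps/day relative to usual care (arm 3), years 1 and 2
    arm_effects: Dict[Tuple[int, int], float] = field(
        default_factory=lambda: {(1, 1): 700.0, (1, 2): 350.0, (2, 1): 450.0, (2, 2): 200.0}
    )

    # weather -> activity coefficients (on the log scale)
    temp_coef: float = 0.0
    rain_coef: float = 0.0
    sun_coef: float = 0.0
    daylength_coef: float = 0.0

    # wear / missingness
    mechanism: str = "mcar"  # mcar | mar | mnar
    p_missing: float = 0.1
    wear_beta: Tuple[float, float] = (2.2, 2.0)
    cutoff_minutes: float = DEFAULT_CUTOFF_MINUTES
    mar_rain: float = 0.5
    mar_sun: float = -0.1
    mar_bmi: float = 0.03
    mar_weekend: float = 0.3
    mnar_strength: float = 1.0

    # substitution support
    extra_week_prob: float = 0.0
    week2_log_shift: float = 0.0

    # calendar / geography
    latitude: float = 51.4
    start_year: int = 2013
    n_regions: int = 4
    epoch_len: int = 5

    def validate(self) -> "SimConfig":
        if self.n_participants < 3:
            raise ParameterError("need at least 3 participants")
        if self.mechanism not in ("mcar", "mar", "mnar"):
            raise ParameterError(f"unknown mechanism {self.mechanism!r}")
        for rate in (self.p_missing, self.extra_week_prob):
            if not 0.0 <= rate <= 1.0:
                raise ParameterError(f"rate {rate} outside [0, 1]")
        cov = np.asarray(self.year_cov, dtype=float)
        if np.linalg.det(cov) <= 0 or cov[0, 0] <= 0:
            raise ParameterError("year_cov must be positive definite")
        if len(self.weekday_effects) != 7:
            raise ParameterError("weekday_effects must have 7 entries")
        return self


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated trial."""

    complete_days: pd.DataFrame  # full-wear counts for every cell
    control_means: Dict[int, float]  # E[week-average | arm 3] per year
    arm_shifts: Dict[Tuple[int, int], float]  # calibrated log-scale shifts
    config: SimConfig

    def true_contrast(self, arm: int, year: int) -> float:
        """Generating steps/day difference vs usual care (exact by calibration)."""
        return float(self.config.arm_effects.get((arm, year), 0.0))


def _arm_cov(config: SimConfig, arm: int) -> np.ndarray:
    if config.arm_year_cov and arm in config.arm_year_cov:
        return np.asarray(config.arm_year_cov[arm], dtype=float)
    return np.asarray(config.year_cov, dtype=float)


# ---------------------------------------------------------------------------
# weather


def _weather(dates: np.ndarray, latitude: float, rng: np.random.Generator):
    """Seasonal weather with naturally-correlated auxiliaries.

    ``dates`` is an array of numpy datetime64[D]. Returns a dict of arrays:
    temperature, sqrt_rainfall, sunshine, daylength.
    """
    doy = (dates - dates.astype("datetime64[Y]")).astype(int) + 1
    season = np.cos(2.0 * np.pi * (doy - 197) / 365.25)  # peak mid-July
    daylength = np.array(
        [compute_daylength(latitude, float(d)) for d in doy]
    )
    temperature = 11.0 + 8.0 * season + rng.normal(0.0, 3.0, size=doy.size)
    sunshine = np.clip(
        0.35 * daylength + 1.5 * season + rng.normal(0.0, 2.0, size=doy.size),
        0.0,
        daylength,
    )
    rain_mm = rng.exponential(2.0, size=doy.size) * (1.0 - 0.25 * season)
    sqrt_rainfall = np.sqrt(rain_mm)
    return {
        "temperature": temperature,
        "sqrt_rainfall": sqrt_rainfall,
        "sunshine": sunshine,
        "daylength": daylength,
    }


def _weather_factor(config: SimConfig, year: int, n_mc: int = 50000) -> float:
    """E[exp(coef . weather)] over the year's calendar, by Monte Carlo."""
    coefs = np.array(
        [config.temp_coef, config.rain_coef, config.sun_coef, config.daylength_coef]
    )
    if np.all(coefs == 0.0):
        return 1.0
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 424242, year]))
    start = np.datetime64(f"{config.start_year + year}-01-01")
    offs = rng.integers(0, 365, size=n_mc)
    dates = start + offs.astype("timedelta64[D]")
    w = _weather(dates, config.latitude, rng)
    lin = sum(c * w[k] for c, k in zip(coefs, ("temperature", "sqrt_rainfall", "sunshine", "daylength")))
    return float(np.mean(np.exp(lin)))


def expected_control_mean(config: SimConfig, year: int) -> float:
    """E[week-average steps/day] in the usual-care arm for ``year`` in {1, 2}."""
    cov3 = _arm_cov(config, 3)
    var = (
        config.participant_sd**2
        + (config.baseline_week_sd**2 if year == 0 else cov3[year - 1, year - 1])
        + config.sigma_day**2
    )
    base = config.baseline_log_mean + config.year_effects[year]
    fw = _weather_factor(config, year)
    per_day = [np.exp(base + wk + 0.5 * var) * fw for wk in config.weekday_effects]
    return float(np.mean(per_day))


def _calibrate_arm_shifts(config: SimConfig) -> Tuple[Dict[Tuple[int, int], float], Dict[int, float]]:
    """Log-scale shifts g so that the arm-vs-control week-average difference
    equals the configured steps/day exactly."""
    control = {j: expected_control_mean(config, j) for j in (1, 2)}
    shifts: Dict[Tuple[int, int], float] = {}
    for (arm, year), delta_steps in config.arm_effects.items():
        if arm not in (1, 2) or year not in (1, 2):
            raise ParameterError(f"arm_effects key {(arm, year)} invalid")
        cov_a = _arm_cov(config, arm)
        cov_3 = _arm_cov(config, 3)
        # expected arm mean with zero shift (variance may differ by arm)
        ratio_var = 0.5 * (cov_a[year - 1, year - 1] - cov_3[year - 1, year - 1])
        ey_a0 = control[year] * np.exp(ratio_var)
        target = control[year] + delta_steps
        if target <= 0:
            raise ParameterError("arm effect drives the expected mean non-positive")
        shifts[(arm, year)] = float(np.log(target / ey_a0))
    return shifts, control


# ---------------------------------------------------------------------------
# main generator


def simulate_trial(config: SimConfig, epochs: bool = False):
    """Generate a trial.

    Returns ``(dataset, truth)`` or ``(dataset, truth, streams)`` when
    ``epochs`` is requested, where ``streams`` is a list of
    :class:`~stepmi.accel.EpochStream` (one per generated day; use small n).
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    s_parts, s_latent, s_weather, s_wear, s_epochs = [
        np.random.default_rng(c) for c in root.spawn(5)
    ]
    n = config.n_participants

    # --- participants -----------------------------------------------------
    ids = np.array([f"P{i:05d}" for i in range(1, n + 1)])
    alloc = np.array(config.allocation, dtype=float)
    arm_pool = np.concatenate(
        [np.full(int(np.floor(n * a / alloc.sum())), i + 1) for i, a in enumerate(alloc)]
    )
    while arm_pool.size < n:  # fill remainder cycling 1,2,3
        arm_pool = np.append(arm_pool, arm_pool.size % 3 + 1)
    arm = s_parts.permutation(arm_pool.astype(int))
    female = s_parts.integers(0, 2, size=n)
    age = np.round(s_parts.normal(70.0, 8.0, size=n), 1)
    region = np.array([f"R{r}" for r in s_parts.integers(1, config.n_regions + 1, size=n)])
    bmi = np.round(np.clip(s_parts.normal(31.0, 5.0, size=n), 16.0, 60.0), 1)
    participants = pd.DataFrame(
        {
            "participant_id": ids,
            "arm": arm,
            "female": female,
            "age": age,
            "region": region,
            "bmi": bmi,
        }
    )

    shifts, control_means = _calibrate_arm_shifts(config)

    # --- latent activity --------------------------------------------------
    a_i = s_latent.normal(0.0, config.participant_sd, size=n)
    u0 = s_latent.normal(0.0, config.baseline_week_sd, size=n)
    u12 = np.empty((n, 2))
    for a in (1, 2, 3):
        idx = np.flatnonzero(arm == a)
        if idx.size:
            u12[idx] = s_latent.multivariate_normal(
                np.zeros(2), _arm_cov(config, a), size=idx.size
            )

    # --- cell grid --------------------------------------------------------
    rows = []
    for j in (0, 1, 2):
        year_start = np.datetime64(f"{config.start_year + j}-01-01")
        start_off = s_latent.integers(0, 352, size=n)
        starts = year_start + start_off.astype("timedelta64[D]")
        # align to Monday so day-of-week labels match the calendar
        # 1970-01-01 is a Thursday; map to 0=Monday
        wd = ((starts.astype("datetime64[D]").view("int64") + 3) % 7).astype(int)
        starts = starts - wd.astype("timedelta64[D]")
        week2 = s_latent.random(n) < config.extra_week_prob
        for w in (1, 2):
            sel = np.ones(n, dtype=bool) if w == 1 else week2
            if not sel.any():
                continue
            for k in range(1, 8):
                dates = starts[sel] + np.timedelta64((w - 1) * 7 + (k - 1), "D")
                rows.append(
                    pd.DataFrame(
                        {
                            "pidx": np.flatnonzero(sel),
                            "year": j,
                            "week": w,
                            "day_of_week": k,
                            "date": dates,
                        }
                    )
                )
    grid = pd.concat(rows, ignore_index=True)

    weather = _weather(grid["date"].to_numpy("datetime64[D]"), config.latitude, s_weather)
    for key, arr in weather.items():
        grid[key] = arr

    pidx = grid["pidx"].to_numpy()
    j_arr = grid["year"].to_numpy()
    k_arr = grid["day_of_week"].to_numpy()
    wk_arr = grid["week"].to_numpy()

    g_shift = np.zeros(len(grid))
    for (a, yr), g in shifts.items():
        g_shift += np.where((arm[pidx] == a) & (j_arr == yr), g, 0.0)
    u_year = np.where(j_arr == 0, u0[pidx], u12[pidx, np.maximum(j_arr - 1, 0)])
    weather_lin = (
        config.temp_coef * grid["temperature"].to_numpy()
        + config.rain_coef * grid["sqrt_rainfall"].to_numpy()
        + config.sun_coef * grid["sunshine"].to_numpy()
        + config.daylength_coef * grid["daylength"].to_numpy()
    )
    e_day = s_latent.normal(0.0, config.sigma_day, size=len(grid))
    log_full = (
        config.baseline_log_mean
        + np.asarray(config.year_effects)[j_arr]
        + g_shift
        + np.asarray(config.weekday_effects)[k_arr - 1]
        + weather_lin
        + a_i[pidx]
        + u_year
        + e_day
        + np.where(wk_arr == 2, config.week2_log_shift, 0.0)
    )
    full_count = np.rint(np.exp(log_full)).astype(np.int64)

    # --- wear / missingness ----------------------------------------------
    z_latent = (a_i[pidx] + u_year + e_day) / np.sqrt(
        config.participant_sd**2 + config.baseline_week_sd**2 + config.sigma_day**2
    )
    eta = _logit(np.clip(config.p_missing, 1e-9, 1 - 1e-9)) * np.ones(len(grid))
    if config.mechanism in ("mar", "mnar"):
        lin = (
            config.mar_rain * grid["sqrt_rainfall"].to_numpy()
            + config.mar_sun * grid["sunshine"].to_numpy()
            + config.mar_bmi * bmi[pidx]
            + config.mar_weekend * (k_arr >= 6)
        )
        eta += lin - lin.mean()
    if config.mechanism == "mnar":
        eta += -config.mnar_strength * z_latent
    p_miss = 1.0 / (1.0 + np.exp(-eta)) if config.mechanism != "mcar" else np.full(
        len(grid), config.p_missing
    )
    nonworn = s_wear.random(len(grid)) < p_miss

    wear = np.zeros(len(grid))
    worn = ~nonworn
    frac = s_wear.beta(config.wear_beta[0], config.wear_beta[1], size=len(grid))
    wear[worn] = np.rint(MINUTES_PER_DAY * frac[worn])
    wear[worn] = np.maximum(wear[worn], 1.0)
    # non-wear gaps shorter than the 60-min run threshold are undetectable
    wear[worn & (wear > MINUTES_PER_DAY - 60)] = MINUTES_PER_DAY

    status = np.where(
        wear == 0,
        STATUS_MISSING,
        np.where(wear < config.cutoff_minutes, STATUS_PARTIAL, STATUS_OBSERVED),
    )
    recorded = np.where(status == STATUS_OBSERVED, full_count, 0).astype(np.int64)
    part = status == STATUS_PARTIAL
    if part.any():
        # activity accrues proportionally to worn time -> right-censoring
        frac_rec = np.floor(full_count[part] * wear[part] / MINUTES_PER_DAY)
        guard = np.floor(wear[part] / 59.0) + 2  # keeps epoch streams reconstructable
        recorded[part] = np.minimum(
            full_count[part], np.maximum(frac_rec, guard)
        ).astype(np.int64)

    days = pd.DataFrame(
        {
            "participant_id": ids[pidx],
            "year": j_arr,
            "week": wk_arr,
            "day_of_week": k_arr,
            "step_count": recorded,
            "wear_minutes": wear,
            "status": status,
        }
    )

    aux = grid.assign(participant_id=ids[pidx])[
        [
            "participant_id",
            "year",
            "week",
            "day_of_week",
            "date",
            "temperature",
            "sqrt_rainfall",
            "sunshine",
            "daylength",
        ]
    ].copy()
    aux["date"] = aux["date"].astype(str)

    dataset = TrialDataset(days=days, participants=participants, auxiliaries=aux)
    dataset.validate()

    complete = pd.DataFrame(
        {
            "participant_id": ids[pidx],
            "year": j_arr,
            "week": wk_arr,
            "day_of_week": k_arr,
            "full_count": full_count,
            "log_full": log_full,
            "wear_minutes": wear,
            "status": status,
        }
    )
    truth = SimTruth(
        complete_days=complete,
        control_means=control_means,
        arm_shifts=shifts,
        config=config,
    )

    if not epochs:
        return dataset, truth
    streams = [
        make_epoch_stream(
            participant_id=ids[pidx[i]],
            year=int(j_arr[i]),
            week=int(wk_arr[i]),
            day_of_week=int(k_arr[i]),
            wear_minutes=float(wear[i]),
            step_count=int(recorded[i]),
            epoch_len=config.epoch_len,
            rng=s_epochs,
        )
        for i in range(len(grid))
    ]
    return dataset, truth, streams


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


# ---------------------------------------------------------------------------
# epoch synthesis


def make_epoch_stream(
    participant_id: str,
    year: int,
    week: int,
    day_of_week: int,
    wear_minutes: float,
    step_count: int,
    epoch_len: int = 5,
    rng: Optional[np.random.Generator] = None,
) -> EpochStream:
    """Build a 24-h epoch stream consistent with a day record.

    The non-worn time is one or two zero runs of >= 60 min at the day's
    edges; worn time holds the recorded steps spread so that no internal
    zero run reaches 60 min and the worn block starts/ends with activity,
    so wear time is reconstructed exactly by non-wear detection.
    """
    per_min = 60 // epoch_len
    n_epochs = 86400 // epoch_len
    steps = np.zeros(n_epochs, dtype=np.int64)
    w = int(round(wear_minutes))
    if w == 0:
        return EpochStream(participant_id, year, day_of_week, steps, week, epoch_len)
    nw = MINUTES_PER_DAY - w
    if 0 < nw < 60:
        raise ParameterError("non-wear gaps under 60 min cannot be represented")
    if nw >= 120:
        head = nw // 2 if rng is None else int(rng.integers(60, nw - 59))
        head = min(max(head, 60), nw - 60)
    elif nw >= 60:
        head = nw
    else:
        head = 0
    start = head * per_min
    worn_epochs = w * per_min

    q, r = divmod(int(step_count), w)
    minute_totals = np.full(w, q, dtype=np.int64)
    if r:
        # spacing >= 1 minute, so rounding keeps the positions distinct and
        # (for r >= 2) the worn block's first/last minutes active
        idx = np.round(np.linspace(0, w - 1, r)).astype(int)
        minute_totals[idx] += 1
    # worn block must begin and end with activity
    if minute_totals[0] == 0 and minute_totals.sum() > 0:
        src = np.flatnonzero(minute_totals)[0]
        minute_totals[0] += 1
        minute_totals[src] -= 1
    if minute_totals[-1] == 0 and minute_totals.sum() > 1:
        src = np.flatnonzero(minute_totals)[-1]
        minute_totals[-1] += 1
        minute_totals[src] -= 1
    steps[start : start + worn_epochs : per_min] = minute_totals
    # the block must also end on an active epoch, else the trailing sub-minute
    # zeros merge into the following non-wear run
    last_first = start + (w - 1) * per_min
    if steps[last_first] > 0 and per_min > 1:
        steps[last_first] -= 1
        steps[start + worn_epochs - 1] += 1
    return EpochStream(participant_id, year, day_of_week, steps, week, epoch_len)


def epoch_streams_frame(streams: List[EpochStream]) -> pd.DataFrame:
    """Long epoch table (participant_id, year, week, day_of_week,
    epoch_index, steps) from a list of streams."""
    frames = []
    for s in streams:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "year": s.year,
                    "week": s.week,
                    "day_of_week": s.day_of_week,
                    "epoch_index": np.arange(s.steps.size),
                    "steps": s.steps,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
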