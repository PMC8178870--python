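"""Multiple imputation of log daily step counts by chained equations with
interval-censored (Tobit) regression.

Each cell carries a log-scale interval: observed days are degenerate points,
partial days are bounded below by their recorded count, missing days are
unbounded below; all incomplete cells share an upper limit above the largest
observed count. Imputation cycles through the 21 (year, weekday) columns,
fitting an interval regression of each column on the other days, the
analysis covariates and (optionally) auxiliary variables, then redrawing the
incomplete cells from the truncated posterior predictive, separately per arm.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .accel import STATUS_MISSING, STATUS_OBSERVED, STATUS_PARTIAL
from .errors import (
    ConvergenceError,
    MalformedInputError,
    ParameterError,
    RankDeficiencyError,
)
from .trial_data import AUX_VARS, TrialDataset

_LOG_2PI = float(np.log(2.0 * np.pi))

YEARS = (0, 1, 2)
DAYS_OF_WEEK = tuple(range(1, 8))
N_CELLS = 21  # 3 years x 7 days
CELL_INDEX = {(j, k): j * 7 + (k - 1) for j in YEARS for k in DAYS_OF_WEEK}


@dataclass
class ImputationSpec:
    """Settings for chained imputation."""

    m: int = 20
    cycles: int = 10
    seed: int = 0
    log_offset: float = 1.0
    upper_factor: float = 1.5
    impute_partial_as_censored: bool = True
    use_auxiliaries: bool = True
    pool_arms: bool = False
    param_draw: str = "asymptotic"  # or "bootstrap"
    max_iter: int = 200
    store_diagnostics: bool = False

    def validate(self) -> "ImputationSpec":
        if self.m < 2:
            raise ParameterError(f"number of imputations m must be >= 2, got {self.m}")
        if self.cycles < 1:
            raise ParameterError(f"cycles must be >= 1, got {self.cycles}")
        if self.log_offset < 0:
            raise ParameterError("log_offset must be non-negative")
        if self.param_draw not in ("asymptotic", "bootstrap"):
            raise ParameterError(f"unknown param_draw: {self.param_draw!r}")
        return self


@dataclass
class ImputedSet:
    """M completed day-level log-count tables plus the bounds used.

    ``data`` is long: columns imp (1..M), participant_id, year, day_of_week,
    log_steps (on the log(count + offset) scale). ``bounds`` carries one row
    per cell with its status and [lower, upper] interval.
    """

    data: pd.DataFrame
    bounds: pd.DataFrame
    spec: ImputationSpec
    diagnostics: Optional[list] = None

    @property
    def m(self) -> int:
        return int(self.data["imp"].max())

    @property
    def log_offset(self) -> float:
        return self.spec.log_offset


# ---------------------------------------------------------------------------
# bounds


def build_bounds(dataset: TrialDataset, spec: ImputationSpec) -> pd.DataFrame:
    """Per-cell log-scale intervals for the measurement-week days.

    Observed: degenerate at log(count + offset). Partial (when imputed as
    censored): [log(count + offset), U]. Missing: (-inf, U]. When
    ``spec.impute_partial_as_censored`` is off, partial cells get
    missing-style bounds (their recorded counts are discarded).
    U = log(upper_factor * max observed count + offset).
    """
    spec.validate()
    days = dataset.week1_days
    obs = days[days["status"] == STATUS_OBSERVED]
    if len(obs) == 0:
        raise MalformedInputError("no observed days: cannot set the imputation upper limit")
    off = spec.log_offset
    upper = float(np.log(spec.upper_factor * obs["step_count"].max() + off))

    out = days[["participant_id", "year", "day_of_week", "status", "step_count"]].copy()
    logged = np.log(out["step_count"].to_numpy(dtype=float) + off)
    status = out["status"].to_numpy()
    lower = np.where(status == STATUS_OBSERVED, logged, -np.inf)
    hi = np.where(status == STATUS_OBSERVED, logged, upper)
    if spec.impute_partial_as_censored:
        is_partial = status == STATUS_PARTIAL
        zero_partial = is_partial & (out["step_count"].to_numpy() == 0)
        if zero_partial.any():
            warnings.warn(
                f"{int(zero_partial.sum())} partial day(s) with zero recorded steps "
                "treated as missing (a zero lower bound carries no information)",
                stacklevel=2,
            )
        informative = is_partial & ~zero_partial
        lower = np.where(informative, logged, lower)
    out["lower"] = lower
    out["upper"] = hi
    bad = out["lower"] > out["upper"]
    if bad.any():
        raise MalformedInputError("cell with lower bound above the upper limit")
    return out.drop(columns="step_count")


# ---------------------------------------------------------------------------
# interval (Tobit) regression


@dataclass
class IntervalFit:
    """Maximum-likelihood interval-regression fit.

    ``params`` stacks (beta, log sigma); ``cov`` is the observed-information
    covariance of ``params``.
    """

    beta: np.ndarray
    sigma: float
    params: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    converged: bool
    X: np.ndarray = field(repr=False, default=None)
    lower: np.ndarray = field(repr=False, default=None)
    upper: np.ndarray = field(repr=False, default=None)


def _log_ndtr_diff(zl: np.ndarray, zu: np.ndarray) -> np.ndarray:
    """log(Phi(zu) - Phi(zl)) computed stably for zl < zu (zl may be -inf)."""
    out = np.empty_like(zu, dtype=float)
    neg = zu <= 0
    pos = ~neg & (zl >= 0)
    mid = ~neg & ~pos
    if neg.any():
        a, b = zl[neg], zu[neg]
        lb = special.log_ndtr(b)
        la = special.log_ndtr(a)
        out[neg] = lb + np.log1p(-np.exp(np.minimum(la - lb, -1e-12)))
    if pos.any():
        a, b = -zu[pos], -zl[pos]
        lb = special.log_ndtr(b)
        la = special.log_ndtr(a)
        out[pos] = lb + np.log1p(-np.exp(np.minimum(la - lb, -1e-12)))
    if mid.any():
        with np.errstate(divide="ignore"):
            out[mid] = np.log(special.ndtr(zu[mid]) - special.ndtr(zl[mid]))
    # floor keeps a transiently absurd iterate finite for the optimizer
    return np.maximum(out, -700.0)


def _interval_nll_grad(theta, X, lower, upper, exact):
    """Negative log-likelihood and gradient for theta = (beta, log sigma)."""
    beta, log_s = theta[:-1], theta[-1]
    s = np.exp(log_s)
    mu = X @ beta
    nll = 0.0
    grad_beta = np.zeros(X.shape[1])
    grad_logs = 0.0

    if exact.any():
        z = (lower[exact] - mu[exact]) / s
        nll += 0.5 * np.sum(z * z) + exact.sum() * (log_s + 0.5 * _LOG_2PI)
        Xe = X[exact]
        grad_beta -= Xe.T @ z / s
        grad_logs += np.sum(1.0 - z * z)

    cen = ~exact
    if cen.any():
        lo, hi = lower[cen], upper[cen]
        zl = np.where(np.isneginf(lo), -np.inf, (lo - mu[cen]) / s)
        zu = np.where(np.isposinf(hi), np.inf, (hi - mu[cen]) / s)
        logD = _log_ndtr_diff(zl, zu)
        nll -= np.sum(logD)

        def _phi_ratio(z):
            r = np.zeros_like(logD)
            fin = np.isfinite(z)
            r[fin] = np.exp(-0.5 * z[fin] ** 2 - 0.5 * _LOG_2PI - logD[fin])
            return r

        ru, rl = _phi_ratio(zu), _phi_ratio(zl)
        grad_beta += X[cen].T @ (ru - rl) / s
        zu_f = np.where(np.isfinite(zu), zu, 0.0)
        zl_f = np.where(np.isfinite(zl), zl, 0.0)
        grad_logs += np.sum(zu_f * ru - zl_f * rl)

    return nll, np.concatenate([grad_beta, [grad_logs]])


def _check_rank(X: np.ndarray, names=None):
    p = X.shape[1]
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the columns implicated via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        dropped = sorted(piv[rank:].tolist())
        labels = [names[i] if names else i for i in dropped]
        raise RankDeficiencyError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"offending columns: {labels}",
            columns=labels,
        )


def fit_interval_regression(
    X: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    start: Optional[np.ndarray] = None,
    max_iter: int = 200,
    column_names=None,
    compute_cov: bool = True,
) -> IntervalFit:
    """ML fit of the Gaussian interval-regression model.

    Rows with ``lower == upper`` are exact observations contributing normal
    densities; other rows contribute Phi differences over [lower, upper]
    (either side may be infinite).
    """
    X = np.asarray(X, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    n, p = X.shape
    if lower.shape != (n,) or upper.shape != (n,):
        raise MalformedInputError("bounds must be one interval per design row")
    if np.any(lower > upper):
        raise MalformedInputError("found a row with lower > upper")
    if n < p + 2:
        raise MalformedInputError(
            f"need at least p + 2 = {p + 2} rows with informative intervals, got {n}"
        )
    _check_rank(X, column_names)
    exact = np.isfinite(lower) & (lower == upper)

    # precondition: centre/scale non-constant columns (folding the shift into
    # the first constant column when one exists) so L-BFGS sees a
    # well-conditioned problem; estimates are mapped back afterwards
    sd = X.std(axis=0)
    mu = X.mean(axis=0)
    const = sd < 1e-12
    i0 = int(np.flatnonzero(const)[0]) if const.any() else None
    scale = np.where(const, 1.0, sd)
    shift = np.where(const, 0.0, mu if i0 is not None else 0.0)
    Xs = (X - shift) / scale
    # theta_orig = T @ theta_scaled
    T = np.eye(p + 1)
    for j in range(p):
        if not const[j]:
            T[j, j] = 1.0 / scale[j]
            if i0 is not None:
                c0 = X[0, i0]  # constant column value (usually 1)
                T[i0, j] = -shift[j] / (scale[j] * c0)

    if start is None:
        y0 = np.where(exact, lower, np.nan)
        with np.errstate(invalid="ignore"):
            fill = np.nanmean(y0) if exact.any() else 0.0
            mid = np.where(
                np.isfinite(lower) & np.isfinite(upper), 0.5 * (lower + upper), fill
            )
        y_fill = np.where(exact, lower, np.where(np.isfinite(lower), lower, mid))
        beta0, *_ = np.linalg.lstsq(Xs, y_fill, rcond=None)
        resid = y_fill - Xs @ beta0
        s0 = max(float(np.std(resid)), 1e-3)
        start_s = np.concatenate([beta0, [np.log(s0)]])
    else:
        start_s = np.linalg.solve(T, np.asarray(start, dtype=float))

    # keep sigma away from the degenerate boundary (possible when the exact
    # rows alone are interpolable by the design)
    box = [(None, None)] * p + [(np.log(1e-6), 50.0)]
    res = optimize.minimize(
        _interval_nll_grad,
        start_s,
        args=(Xs, lower, upper, exact),
        jac=True,
        method="L-BFGS-B",
        bounds=box,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7},
    )
    if not np.isfinite(res.fun):
        raise ConvergenceError("interval regression objective is non-finite", res.fun)
    if not res.success and np.linalg.norm(res.jac) > 1e-3 * (1 + abs(res.fun)):
        # one longer restart before giving up
        res2 = optimize.minimize(
            _interval_nll_grad,
            res.x,
            args=(Xs, lower, upper, exact),
            jac=True,
            method="L-BFGS-B",
            bounds=box,
            options={"maxiter": 10 * max_iter, "ftol": 1e-13, "gtol": 1e-8},
        )
        if res2.fun <= res.fun:
            res = res2
        if not res.success and np.linalg.norm(res.jac) > 1e-2 * (1 + abs(res.fun)):
            raise ConvergenceError(
                f"interval regression failed to converge after {max_iter} iterations",
                last_objective=float(res.fun),
            )
    theta = T @ res.x
    if compute_cov:
        cov_s = _observed_information_cov(res.x, Xs, lower, upper, exact)
        cov = T @ cov_s @ T.T
    else:
        cov = None
    return IntervalFit(
        beta=theta[:-1].copy(),
        sigma=float(np.exp(theta[-1])),
        params=theta,
        cov=cov,
        loglik=float(-res.fun),
        n=n,
        converged=bool(res.success),
        X=X,
        lower=lower,
        upper=upper,
    )


def _observed_information_cov(theta, X, lower, upper, exact) -> np.ndarray:
    """Covariance from finite differences of the analytic gradient."""
    k = theta.size
    H = np.empty((k, k))
    h = 1e-5 * (1.0 + np.abs(theta))
    for i in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h[i]
        tm[i] -= h[i]
        _, gp = _interval_nll_grad(tp, X, lower, upper, exact)
        _, gm = _interval_nll_grad(tm, X, lower, upper, exact)
        H[i] = (gp - gm) / (2.0 * h[i])
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H + 1e-8 * np.eye(k))
    return cov


# ---------------------------------------------------------------------------
# posterior draws


def draw_parameters(fit: IntervalFit, rng: np.random.Generator) -> Tuple[np.ndarray, float]:
    """One (beta*, sigma*) draw from the asymptotic-normal posterior."""
    cov = fit.cov
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(0.5 * (cov + cov.T))
        L = V @ np.diag(np.sqrt(np.clip(w, 1e-12, None)))
    theta = fit.params + L @ rng.standard_normal(fit.params.size)
    return theta[:-1], float(np.exp(theta[-1]))


def draw_parameters_bootstrap(
    fit: IntervalFit, rng: np.random.Generator
) -> Tuple[np.ndarray, float]:
    """One parameter draw by refitting on a nonparametric bootstrap resample."""
    n = fit.n
    idx = rng.integers(0, n, size=n)
    bfit = fit_interval_regression(
        fit.X[idx],
        fit.lower[idx],
        fit.upper[idx],
        start=fit.params,
        compute_cov=False,
    )
    return bfit.beta, bfit.sigma


def sample_truncated_normal(
    mu: np.ndarray,
    sigma: float,
    lower: np.ndarray,
    upper: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draws from N(mu, sigma^2) truncated to [lower, upper] (either side may
    be infinite). Falls back to exponential-rejection tail sampling rather
    than clamping when the interval sits in an extreme tail."""
    mu = np.asarray(mu, dtype=float)
    lower = np.broadcast_to(np.asarray(lower, dtype=float), mu.shape)
    upper = np.broadcast_to(np.asarray(upper, dtype=float), mu.shape)
    a = (lower - mu) / sigma
    b = (upper - mu) / sigma
    draws = stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, random_state=rng)
    draws = np.asarray(draws, dtype=float).reshape(mu.shape)
    bad = ~np.isfinite(draws) | (draws < lower) | (draws > upper)
    if bad.any():
        for i in np.flatnonzero(bad):
            draws.flat[i] = mu.flat[i] + sigma * _tail_draw(a.flat[i], b.flat[i], rng)
    return draws


def _tail_draw(a: float, b: float, rng: np.random.Generator) -> float:
    """Robert (1995) exponential-rejection draw from a standard normal
    truncated to [a, b] when the interval lies deep in a tail."""
    if a > 0:  # right tail
        alpha = 0.5 * (a + np.sqrt(a * a + 4.0))
        for _ in range(10000):
            z = a + rng.exponential(1.0 / alpha)
            if z <= b and rng.random() <= np.exp(-0.5 * (z - alpha) ** 2):
                return float(z)
        raise ConvergenceError("tail sampling failed to accept a draw")
    if b < 0:  # left tail: reflect
        return -_tail_draw(-b, -a, rng)
    # interval straddles 0: plain rejection from N(0,1)
    for _ in range(10000):
        z = rng.standard_normal()
        if a <= z <= b:
            return float(z)
    raise ConvergenceError("truncated-normal rejection failed")


def draw_imputations(
    fit: IntervalFit,
    X_incomplete: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    rng: np.random.Generator,
    param_draw: str = "asymptotic",
) -> np.ndarray:
    """Posterior-predictive draws for incomplete cells: one parameter draw
    from the approximate posterior, then truncated-normal draws per row."""
    if param_draw == "bootstrap":
        beta_s, sigma_s = draw_parameters_bootstrap(fit, rng)
    else:
        beta_s, sigma_s = draw_parameters(fit, rng)
    mu = np.asarray(X_incomplete, dtype=float) @ beta_s
    return sample_truncated_normal(mu, sigma_s, lower, upper, rng)


# ---------------------------------------------------------------------------
# chained equations


def _covariate_matrix(participants: pd.DataFrame, age_center: float, spec: ImputationSpec,
                      include_arm_dummies: bool):
    """Static covariate block: intercept, female, centred age, region dummies,
    optional arm dummies (pooled fits), optional BMI (with auxiliaries)."""
    cols = [np.ones(len(participants))]
    names = ["intercept"]
    cols.append(participants["female"].to_numpy(dtype=float))
    names.append("female")
    cols.append(participants["age"].to_numpy(dtype=float) - age_center)
    names.append("age")
    regions = sorted(participants["region"].astype(str).unique())
    for r in regions[1:]:  # first level (alphabetical) is the reference
        cols.append((participants["region"].astype(str) == r).to_numpy(dtype=float))
        names.append(f"region[{r}]")
    if include_arm_dummies:
        for a in (1, 2):
            cols.append((participants["arm"] == a).to_numpy(dtype=float))
            names.append(f"arm{a}")
    if spec.use_auxiliaries:
        cols.append(participants["bmi"].to_numpy(dtype=float))
        names.append("bmi")
    return np.column_stack(cols), names


def _aux_array(dataset: TrialDataset, ids: np.ndarray) -> np.ndarray:
    """A[n, 21, 4] of day-level auxiliaries aligned to the cell grid."""
    aux = dataset.auxiliaries
    if aux is None:
        raise MalformedInputError("scenario uses auxiliaries but the dataset has none")
    aux = aux[aux["week"] == 1] if "week" in aux.columns else aux
    pivot = aux.set_index(["participant_id", "year", "day_of_week"])[AUX_VARS]
    n = len(ids)
    A = np.empty((n, N_CELLS, len(AUX_VARS)))
    for (j, k), c in CELL_INDEX.items():
        try:
            block = pivot.loc[[(pid, j, k) for pid in ids]].to_numpy()
        except KeyError as e:
            raise MalformedInputError(f"missing auxiliary rows for (year={j}, day={k}): {e}")
        A[:, c, :] = block
    return A


def _day_predictor_block(Y: np.ndarray, col: int):
    """Day-level predictors for the regression of column ``col`` per the
    chained-model structure: baseline columns enter individually when
    imputing baseline days, and as their within-week mean for later years."""
    j = col // 7
    base_cols = list(range(0, 7))
    y1_cols = list(range(7, 14))
    y2_cols = list(range(14, 21))
    if j == 0:
        pred_cols = [c for c in base_cols if c != col] + y1_cols + y2_cols
        names = [f"day{c}" for c in pred_cols]
        return Y[:, pred_cols], names
    base_mean = Y[:, base_cols].mean(axis=1, keepdims=True)
    if j == 1:
        pred_cols = [c for c in y1_cols if c != col] + y2_cols
    else:
        pred_cols = y1_cols + [c for c in y2_cols if c != col]
    block = np.hstack([base_mean, Y[:, pred_cols]])
    names = ["baseline_logmean"] + [f"day{c}" for c in pred_cols]
    return block, names


def _prune_columns(X: np.ndarray, names: List[str]):
    """Drop zero-variance and near-duplicate (|corr| > 0.999) columns,
    keeping the intercept. Returns (X_kept, names_kept, kept_indices)."""
    p = X.shape[1]
    keep = np.ones(p, dtype=bool)
    sd = X.std(axis=0)
    for i in range(1, p):  # column 0 is the intercept
        if sd[i] < 1e-12:
            keep[i] = False
    active = np.flatnonzero(keep)[1:]  # exclude intercept from corr screen
    if active.size > 1:
        sub = X[:, active]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                if keep[active[jj]] and abs(corr[ii, jj]) > 0.999:
                    keep[active[jj]] = False
    idx = np.flatnonzero(keep)
    return X[:, idx], [names[i] for i in idx], idx


def _initialize_cells(Y, incomplete, lower, upper, statuses, rng):
    """Fill incomplete cells by drawing from the observed empirical
    distribution of the same column, respecting the cell bounds."""
    n, C = Y.shape
    for c in range(C):
        inc = incomplete[:, c]
        if not inc.any():
            continue
        pool = Y[(statuses[:, c] == STATUS_OBSERVED), c]
        if pool.size == 0:
            pool = Y[(statuses == STATUS_OBSERVED)]
        if pool.size == 0:
            pool = np.array([0.0])
        draws = rng.choice(pool, size=int(inc.sum()), replace=True)
        lo, hi = lower[inc, c], upper[inc, c]
        eps = 1e-6
        lo_clip = np.where(np.isfinite(lo), lo + eps, -np.inf)
        hi_clip = np.where(np.isfinite(hi), hi - eps, np.inf)
        Y[inc, c] = np.clip(draws, lo_clip, hi_clip)
    return Y


def chained_impute(dataset: TrialDataset, spec: ImputationSpec) -> ImputedSet:
    """Run chained-equations Tobit imputation and return M completed tables.

    Visiting order is Monday..Sunday within each year, years 0, 1, 2; each
    arm is imputed separately unless ``spec.pool_arms``.
    """
    spec.validate()
    dataset.validate()
    bounds = build_bounds(dataset, spec)

    parts = dataset.participants.sort_values("participant_id").reset_index(drop=True)
    ids = parts["participant_id"].to_numpy()
    n = len(ids)
    id_pos = {pid: i for i, pid in enumerate(ids)}

    # wide grids
    lower = np.full((n, N_CELLS), np.nan)
    upper = np.full((n, N_CELLS), np.nan)
    statuses = np.full((n, N_CELLS), "", dtype=object)
    for row in bounds.itertuples(index=False):
        i = id_pos.get(row.participant_id)
        if i is None:
            raise MalformedInputError(f"day record for unknown participant {row.participant_id}")
        c = CELL_INDEX[(row.year, row.day_of_week)]
        lower[i, c] = row.lower
        upper[i, c] = row.upper
        statuses[i, c] = row.status
    if np.isnan(upper).any():
        missing_cells = int(np.isnan(upper).sum())
        raise MalformedInputError(
            f"{missing_cells} (participant, year, day) cells absent from the days table; "
            "every in-window cell must be present (status 'missing' for unworn days)"
        )
    exact = np.isfinite(lower) & (lower == upper)
    incomplete = ~exact
    Y_obs = np.where(exact, lower, np.nan)

    Z, z_names = _covariate_matrix(parts, dataset.age_center or 0.0, spec, spec.pool_arms)
    A = _aux_array(dataset, ids) if spec.use_auxiliaries else None

    if spec.pool_arms:
        groups = [("all", np.arange(n))]
    else:
        groups = [
            (int(a), np.flatnonzero(parts["arm"].to_numpy() == a)) for a in (1, 2, 3)
        ]
        groups = [(a, idx) for a, idx in groups if idx.size]

    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(len(groups) * spec.m)

    records = []
    diagnostics = [] if spec.store_diagnostics else None
    no_incomplete = not incomplete.any()

    for g_i, (label, g_idx) in enumerate(groups):
        Yg_obs = Y_obs[g_idx]
        inc_g = incomplete[g_idx]
        lo_g, hi_g = lower[g_idx], upper[g_idx]
        st_g = statuses[g_idx]
        Zg = Z[g_idx]
        Ag = A[g_idx] if A is not None else None
        max_p = Zg.shape[1] + 20 + (4 if Ag is not None else 0) + 1
        if inc_g.any() and g_idx.size < max_p + 2:
            raise MalformedInputError(
                f"arm group {label!r} has only {g_idx.size} participants for a design of "
                f"~{max_p} columns; consider pool_arms=True"
            )
        for m in range(spec.m):
            rng = np.random.default_rng(children[g_i * spec.m + m])
            Y = Yg_obs.copy()
            if no_incomplete or not inc_g.any():
                Y = np.where(np.isnan(Y), 0.0, Y)
                records.append((label, m + 1, g_idx, Y))
                continue
            Y = _initialize_cells(Y, inc_g, lo_g, hi_g, st_g, rng)
            warm: Dict[int, np.ndarray] = {}
            for cycle in range(spec.cycles):
                for c in range(N_CELLS):
                    inc_col = inc_g[:, c]
                    if not inc_col.any():
                        continue
                    block, b_names = _day_predictor_block(Y, c)
                    parts_X = [Zg, block]
                    names = list(z_names) + b_names
                    if Ag is not None:
                        parts_X.append(Ag[:, c, :])
                        names += AUX_VARS
                    X_full = np.hstack(parts_X)
                    Xp, p_names, kept = _prune_columns(X_full, names)
                    start = warm.get(c)
                    if start is not None and start.size != Xp.shape[1] + 1:
                        start = None
                    fit = fit_interval_regression(
                        Xp,
                        lo_g[:, c],
                        hi_g[:, c],
                        start=start,
                        max_iter=spec.max_iter,
                        column_names=p_names,
                    )
                    warm[c] = fit.params
                    vals = draw_imputations(
                        fit,
                        Xp[inc_col],
                        lo_g[inc_col, c],
                        hi_g[inc_col, c],
                        rng,
                        param_draw=spec.param_draw,
                    )
                    Y[inc_col, c] = vals
                    if diagnostics is not None:
                        diagnostics.append(
                            {
                                "group": label,
                                "imp": m + 1,
                                "cycle": cycle + 1,
                                "cell": c,
                                "params": fit.params.copy(),
                                "sigma": fit.sigma,
                                "names": p_names,
                            }
                        )
            records.append((label, m + 1, g_idx, Y))

    frames = []
    years = np.repeat(YEARS, 7)
    dows = np.tile(DAYS_OF_WEEK, 3)
    for label, m, g_idx, Y in records:
        n_g = g_idx.size
        frames.append(
            pd.DataFrame(
                {
                    "imp": m,
                    "participant_id": np.repeat(ids[g_idx], N_CELLS),
                    "year": np.tile(years, n_g),
                    "day_of_week": np.tile(dows, n_g),
                    "log_steps": Y.ravel(),
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    data = data.sort_values(["imp", "participant_id", "year", "day_of_week"]).reset_index(
        drop=True
    )
    return ImputedSet(data=data, bounds=bounds, spec=spec, diagnostics=diagnostics)
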