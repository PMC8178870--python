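"""Week-averaging, the heteroscedastic-by-arm primary analysis model, and
Rubin's-rules pooling across imputations.

The primary analysis regresses the week-average step count at years 1 and 2
on treatment, year, their interaction, the baseline week average (and its
year interaction), sex, age and region, with the residual pair of each
participant drawn from an arm-specific unstructured 2x2 covariance. Fits
from the M imputed datasets are pooled by Rubin's rules with Barnard-Rubin
degrees of freedom.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, MalformedInputError, ParameterError
from .imputation import ImputedSet

DAYS_PER_WEEK = 7


# ---------------------------------------------------------------------------
# week averaging


def week_average(imputed: Union[ImputedSet, pd.DataFrame], log_offset: Optional[float] = None) -> pd.DataFrame:
    """Per-imputation week-average step counts.

    Accepts an :class:`ImputedSet` (offset taken from it) or a long table
    with columns imp, participant_id, year, log_steps. Daily counts are
    back-transformed as max(exp(log) - offset, 0) then averaged over the 7
    days of each (participant, year).
    """
    if isinstance(imputed, ImputedSet):
        df = imputed.data
        off = imputed.log_offset
    else:
        df = imputed
        if log_offset is None:
            raise ParameterError("log_offset required when passing a plain table")
        off = log_offset
    counts = df.groupby(["imp", "participant_id", "year"]).size()
    if (counts != DAYS_PER_WEEK).any():
        bad = counts[counts != DAYS_PER_WEEK].index[0]
        raise MalformedInputError(
            f"cell {bad} has {counts.loc[bad]} days; post-imputation data must have exactly 7"
        )
    steps = np.maximum(np.exp(df["log_steps"].to_numpy(dtype=float)) - off, 0.0)
    tmp = df[["imp", "participant_id", "year"]].copy()
    tmp["steps"] = steps
    out = (
        tmp.groupby(["imp", "participant_id", "year"], sort=True)["steps"]
        .mean()
        .rename("avg_steps")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# primary analysis fit


@dataclass
class FitResult:
    """One maximum-likelihood fit of the bivariate primary analysis model."""

    params: pd.Series
    cov_params: pd.DataFrame
    sigma: Dict[int, np.ndarray]  # arm -> 2x2 residual covariance
    loglik: float
    n_participants: int
    converged: bool
    n_iter: int

    @property
    def terms(self) -> List[str]:
        return list(self.params.index)


def _primary_design(weeks: pd.DataFrame, participants: pd.DataFrame, age_center: float):
    """Stack one (year1, year2) outcome pair and 2xp design per participant."""
    wide = weeks.pivot(index="participant_id", columns="year", values="avg_steps")
    for y in (0, 1, 2):
        if y not in wide.columns:
            raise MalformedInputError(f"week-average table lacks year {y} rows")
    if wide.isna().any().any():
        raise MalformedInputError("week-average table has missing cells; data must be complete")
    parts = participants.set_index("participant_id").loc[wide.index]
    n = len(wide)
    if n < 2:
        raise MalformedInputError("need at least 2 participants")

    regions = sorted(parts["region"].astype(str).unique())
    arm = parts["arm"].to_numpy()
    # arm dummies only for treatment arms actually present (and only when the
    # data span more than one arm, else the dummy aliases the intercept)
    arm_levels = [a for a in (1, 2) if (arm == a).any()] if len(set(arm)) > 1 else []
    terms = ["intercept", "year2"]
    terms += [f"arm{a}" for a in arm_levels]
    terms += [f"arm{a}:year2" for a in arm_levels]
    terms += ["baseline", "baseline:year2", "female", "age"]
    terms += [f"region[{r}]" for r in regions[1:]]
    p = len(terms)

    baseline = wide[0].to_numpy(dtype=float)
    female = parts["female"].to_numpy(dtype=float)
    age = parts["age"].to_numpy(dtype=float) - age_center

    X = np.zeros((n, 2, p))
    y = np.column_stack([wide[1].to_numpy(dtype=float), wide[2].to_numpy(dtype=float)])
    for r, year2 in ((0, 0.0), (1, 1.0)):
        col = {"intercept": 1.0, "year2": year2, "baseline": baseline,
               "baseline:year2": baseline * year2, "female": female, "age": age}
        for a in arm_levels:
            col[f"arm{a}"] = (arm == a).astype(float)
            col[f"arm{a}:year2"] = col[f"arm{a}"] * year2
        for reg in regions[1:]:
            col[f"region[{reg}]"] = (
                parts["region"].astype(str) == reg
            ).to_numpy(dtype=float)
        for j, t in enumerate(terms):
            X[:, r, j] = col[t]
    return X, y, arm, terms, wide.index.to_numpy()


def fit_primary(
    weeks: pd.DataFrame,
    participants: pd.DataFrame,
    age_center: Optional[float] = None,
    method: str = "ml",
    tol: float = 1e-8,
    max_iter: int = 500,
) -> FitResult:
    """Fit the bivariate heteroscedastic model by iterated GLS.

    ``weeks`` must hold one ``avg_steps`` row per (participant, year) for
    years 0 (baseline covariate), 1 and 2. ``method='reml'`` applies the
    EM-REML hat-matrix correction in the covariance updates; the default is
    straight ML (divisor n per arm).
    """
    if method not in ("ml", "reml"):
        raise ParameterError(f"unknown method {method!r}")
    if age_center is None:
        age_center = float(participants["age"].mean())
    X, y, arm, terms, _ = _primary_design(weeks, participants, age_center)
    n, _, p = X.shape
    arms = sorted(np.unique(arm).tolist())
    for a in arms:
        if (arm == a).sum() < 2:
            raise MalformedInputError(f"arm {a} has fewer than 2 participants")

    groups = {a: np.flatnonzero(arm == a) for a in arms}
    sigma = {a: np.eye(2) * max(float(np.var(y)), 1.0) for a in arms}

    ll_old = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        for a, idx in groups.items():
            Sinv = _inv2(sigma[a])
            Xa, ya = X[idx], y[idx]
            XtVX += np.einsum("nip,ij,njq->pq", Xa, Sinv, Xa, optimize=True)
            XtVy += np.einsum("nip,ij,nj->p", Xa, Sinv, ya, optimize=True)
        try:
            beta = np.linalg.solve(XtVX, XtVy)
            cov_beta = np.linalg.inv(XtVX)
        except np.linalg.LinAlgError as e:
            raise ConvergenceError(f"singular GLS system: {e}")

        ll = 0.0
        new_sigma = {}
        for a, idx in groups.items():
            Xa, ya = X[idx], y[idx]
            r = ya - np.einsum("nip,p->ni", Xa, beta)
            S = r.T @ r / len(idx)
            if method == "reml":
                S = S + np.einsum("nip,pq,njq->ij", Xa, cov_beta, Xa, optimize=True) / len(idx)
            S = 0.5 * (S + S.T)
            if np.linalg.det(S) <= 0 or S[0, 0] <= 0 or S[1, 1] <= 0:
                raise ConvergenceError(
                    f"non-positive-definite covariance update for arm {a}: {S.tolist()}"
                )
            new_sigma[a] = S
            Sinv = _inv2(sigma[a])
            quad = np.einsum("ni,ij,nj->n", r, Sinv, r)
            ll += -0.5 * (
                len(idx) * (2.0 * np.log(2.0 * np.pi) + np.log(np.linalg.det(sigma[a])))
                + quad.sum()
            )
        sigma = new_sigma
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    if not converged:
        raise ConvergenceError(
            f"primary analysis did not converge in {max_iter} iterations", last_objective=ll
        )

    return FitResult(
        params=pd.Series(beta, index=terms),
        cov_params=pd.DataFrame(cov_beta, index=terms, columns=terms),
        sigma=sigma,
        loglik=float(ll),
        n_participants=n,
        converged=True,
        n_iter=it,
    )


def _inv2(S: np.ndarray) -> np.ndarray:
    det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
    return np.array([[S[1, 1], -S[0, 1]], [-S[1, 0], S[0, 0]]]) / det


# ---------------------------------------------------------------------------
# Rubin pooling


@dataclass
class PooledResult:
    """Rubin-pooled fixed effects and variance decomposition."""

    table: pd.DataFrame  # term, estimate, W, B, T, df, t, lo95, hi95
    params: pd.Series
    cov: pd.DataFrame  # total covariance: W_full + (1 + 1/M) B_full
    sigma: Dict[int, np.ndarray]  # per-arm pooled residual covariance
    m: int
    nu_com: float
    estimates: pd.DataFrame  # M x p per-imputation estimates
    within_covs: List[pd.DataFrame]


def barnard_rubin_df(m: int, b: float, t: float, nu_com: float) -> float:
    """Barnard & Rubin (1999) small-sample degrees of freedom."""
    if b <= 0 or t <= 0:
        return float(nu_com)
    lam = (1.0 + 1.0 / m) * b / t
    lam = min(max(lam, 1e-12), 1.0 - 1e-12)
    nu_old = (m - 1) / lam**2
    nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
    return float(1.0 / (1.0 / nu_old + 1.0 / nu_obs))


def _pool_scalar(q: np.ndarray, u: np.ndarray, nu_com: float):
    m = q.size
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    df = barnard_rubin_df(m, b, t, nu_com)
    se = np.sqrt(t)
    tcrit = stats.t.ppf(0.975, df) if np.isfinite(df) else stats.norm.ppf(0.975)
    tval = qbar / se if se > 0 else np.nan
    return qbar, w, b, t, df, tval, qbar - tcrit * se, qbar + tcrit * se


def pool_rubin(fits: List[FitResult]) -> PooledResult:
    """Pool M fits: estimate = mean, T = W + (1 + 1/M) B, Barnard-Rubin df."""
    if len(fits) < 2:
        raise ParameterError("need at least M = 2 fits to pool")
    terms = fits[0].terms
    for f in fits[1:]:
        if f.terms != terms:
            raise MalformedInputError("fits have mismatched coefficient sets")
    m = len(fits)
    Q = np.vstack([f.params.to_numpy() for f in fits])
    covs = [f.cov_params.to_numpy() for f in fits]
    W_full = np.mean(covs, axis=0)
    dev = Q - Q.mean(axis=0)
    B_full = dev.T @ dev / (m - 1)
    T_full = W_full + (1.0 + 1.0 / m) * B_full
    n = fits[0].n_participants
    nu_com = 2.0 * n - len(terms)

    rows = []
    for j, term in enumerate(terms):
        qbar, w, b, t, df, tval, lo, hi = _pool_scalar(
            Q[:, j], np.array([c[j, j] for c in covs]), nu_com
        )
        rows.append(
            {
                "term": term,
                "estimate": qbar,
                "W": w,
                "B": b,
                "T": t,
                "df": df,
                "t": tval,
                "lo95": lo,
                "hi95": hi,
            }
        )
    table = pd.DataFrame(rows)

    arms = fits[0].sigma.keys()
    sigma_pooled = {a: np.mean([f.sigma[a] for f in fits], axis=0) for a in arms}

    return PooledResult(
        table=table,
        params=pd.Series(Q.mean(axis=0), index=terms),
        cov=pd.DataFrame(T_full, index=terms, columns=terms),
        sigma=sigma_pooled,
        m=m,
        nu_com=nu_com,
        estimates=pd.DataFrame(Q, columns=terms),
        within_covs=[pd.DataFrame(c, index=terms, columns=terms) for c in covs],
    )


def contrasts(pooled: PooledResult) -> pd.DataFrame:
    """Arm-vs-usual-care differences in average step count at years 1 and 2.

    Year-1 contrast for arm a is the arm-a coefficient; year-2 adds the
    arm x year2 interaction. Each contrast is pooled scalar-wise across the
    M imputations with its own Barnard-Rubin df.
    """
    terms = list(pooled.params.index)
    p = len(terms)
    Q = pooled.estimates.to_numpy()
    covs = [c.to_numpy() for c in pooled.within_covs]
    rows = []
    for a in (1, 2):
        for year in (1, 2):
            c = np.zeros(p)
            c[terms.index(f"arm{a}")] = 1.0
            if year == 2:
                c[terms.index(f"arm{a}:year2")] = 1.0
            q = Q @ c
            u = np.array([c @ cv @ c for cv in covs])
            qbar, w, b, t, df, tval, lo, hi = _pool_scalar(q, u, pooled.nu_com)
            rows.append(
                {
                    "arm": a,
                    "year": year,
                    "estimate": qbar,
                    "se": np.sqrt(t),
                    "df": df,
                    "lo95": lo,
                    "hi95": hi,
                }
            )
    return pd.DataFrame(rows)
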