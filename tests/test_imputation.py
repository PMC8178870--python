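import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from stepmi.accel import STATUS_MISSING, STATUS_OBSERVED, STATUS_PARTIAL
from stepmi.errors import MalformedInputError, ParameterError, RankDeficiencyError
from stepmi.imputation import (
    ImputationSpec,
    build_bounds,
    chained_impute,
    draw_imputations,
    fit_interval_regression,
    sample_truncated_normal,
)
from stepmi.simulate import SimConfig, simulate_trial
from stepmi.trial_data import TrialDataset

from conftest import full_grid_days, make_participants


class TestBuildBounds:
    def _dataset(self, status_fn, count=8000):
        ids = [f"P{i}" for i in range(1, 5)]
        days = full_grid_days(ids, status_fn, count=count)
        return TrialDataset(days=days, participants=make_participants(ids)).validate()

    def test_observed_degenerate_interval(self):
        ds = self._dataset(lambda p, y, d: STATUS_OBSERVED, count=10000)
        b = build_bounds(ds, ImputationSpec())
        assert (b["lower"] == b["upper"]).all()
        assert b["lower"].iloc[0] == pytest.approx(np.log(10001))

    def test_partial_lower_is_logged_count(self):
        def fn(p, y, d):
            return STATUS_PARTIAL if (p, y, d) == ("P1", 0, 1) else STATUS_OBSERVED

        ds = self._dataset(fn)
        ds.days.loc[
            (ds.days.participant_id == "P1") & (ds.days.year == 0) & (ds.days.day_of_week == 1),
            "step_count",
        ] = 2999
        b = build_bounds(ds, ImputationSpec())
        cell = b.query("participant_id == 'P1' and year == 0 and day_of_week == 1").iloc[0]
        assert cell.lower == pytest.approx(np.log(3000))
        assert cell.upper == pytest.approx(np.log(1.5 * 8000 + 1))

    def test_missing_unbounded_below(self):
        def fn(p, y, d):
            return STATUS_MISSING if (p, y, d) == ("P1", 0, 1) else STATUS_OBSERVED

        b = build_bounds(self._dataset(fn), ImputationSpec())
        cell = b.query("participant_id == 'P1' and year == 0 and day_of_week == 1").iloc[0]
        assert np.isneginf(cell.lower)
        assert np.isfinite(cell.upper)

    def test_zero_count_partial_warns_and_downgrades(self):
        def fn(p, y, d):
            return STATUS_PARTIAL if (p, y, d) == ("P1", 0, 1) else STATUS_OBSERVED

        ds = self._dataset(fn)
        ds.days.loc[
            (ds.days.participant_id == "P1") & (ds.days.year == 0) & (ds.days.day_of_week == 1),
            "step_count",
        ] = 0
        with pytest.warns(UserWarning, match="zero recorded steps"):
            b = build_bounds(ds, ImputationSpec())
        cell = b.query("participant_id == 'P1' and year == 0 and day_of_week == 1").iloc[0]
        assert np.isneginf(cell.lower)

    def test_dismissive_treats_partial_as_missing(self):
        def fn(p, y, d):
            return STATUS_PARTIAL if (p, y, d) == ("P1", 0, 1) else STATUS_OBSERVED

        ds = self._dataset(fn)
        b = build_bounds(ds, ImputationSpec(impute_partial_as_censored=False))
        cell = b.query("participant_id == 'P1' and year == 0 and day_of_week == 1").iloc[0]
        assert np.isneginf(cell.lower)
        assert cell.status == STATUS_PARTIAL  # provenance retained for delta targeting


class TestIntervalRegression:
    def test_censoring_free_limit_equals_ols(self):
        rng = np.random.default_rng(42)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        beta = np.array([2.0, 1.0, -0.5, 0.25])
        y = X @ beta + rng.normal(0, 0.8, n)
        fit = fit_interval_regression(X, y, y)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta, ols, atol=1e-6)
        # ML sigma uses divisor n
        sigma_ml = np.sqrt(np.mean((y - X @ ols) ** 2))
        assert fit.sigma == pytest.approx(sigma_ml, rel=1e-4)

    def test_recovers_beta_with_right_censoring(self):
        rng = np.random.default_rng(7)
        n = 2000
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        beta = np.array([1.0, 0.7, -0.4])
        sigma = 1.0
        y = X @ beta + rng.normal(0, sigma, n)
        thresh = np.quantile(y, 0.7)  # ~30% right-censored
        cen = y > thresh
        lower = np.where(cen, thresh, y)
        upper = np.where(cen, np.inf, y)
        fit = fit_interval_regression(X, lower, upper)
        se = np.sqrt(np.diag(fit.cov)[:3])
        assert np.all(np.abs(fit.beta - beta) < 3 * se)
        assert fit.sigma == pytest.approx(sigma, rel=0.1)

    def test_loglik_matches_quadrature_oracle(self):
        """5-row hand problem: likelihood equals numeric integration."""
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0], [1.0, -1.0], [1.0, 0.5]])
        lower = np.array([0.2, 1.4, -np.inf, 0.0, 1.0])
        upper = np.array([0.2, 1.4, 2.5, 1.0, np.inf])
        fit = fit_interval_regression(X, lower, upper, max_iter=500)
        beta, s = fit.beta, fit.sigma
        ll = 0.0
        for i in range(5):
            mu = X[i] @ beta
            if lower[i] == upper[i]:
                ll += stats.norm.logpdf(lower[i], mu, s)
            else:
                lo = lower[i] if np.isfinite(lower[i]) else mu - 40 * s
                hi = upper[i] if np.isfinite(upper[i]) else mu + 40 * s
                val, _ = integrate.quad(lambda t: stats.norm.pdf(t, mu, s), lo, hi)
                ll += np.log(val)
        assert fit.loglik == pytest.approx(ll, abs=1e-5)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(1)
        n = 30
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        y = rng.normal(size=n)
        with pytest.raises(RankDeficiencyError) as exc:
            fit_interval_regression(X, y, y, column_names=["const", "a", "a_copy"])
        assert exc.value.columns  # at least one named column

    def test_too_few_rows(self):
        X = np.ones((3, 2))
        y = np.zeros(3)
        with pytest.raises(MalformedInputError, match="rows"):
            fit_interval_regression(X, y, y)

    def test_inverted_bounds_rejected(self):
        X = np.ones((10, 1))
        with pytest.raises(MalformedInputError):
            fit_interval_regression(X, np.ones(10), np.zeros(10))


class TestTruncatedDraws:
    def test_unbounded_interval_matches_normal_moments(self, rng):
        mu, sigma = 2.0, 1.5
        x = sample_truncated_normal(np.full(200_000, mu), sigma, -np.inf, np.inf, rng)
        assert x.mean() == pytest.approx(mu, abs=0.02)
        assert x.std() == pytest.approx(sigma, abs=0.02)

    def test_half_line_mean(self, rng):
        mu, sigma = 1.0, 2.0
        x = sample_truncated_normal(np.full(200_000, mu), sigma, mu, np.inf, rng)
        expected = mu + sigma * 0.7978845608
        se = sigma * np.sqrt(1 - 0.7978845608**2) / np.sqrt(len(x))
        assert abs(x.mean() - expected) < 4 * se

    def test_draws_respect_bounds(self, rng):
        lo = np.linspace(-1, 1, 1000)
        hi = lo + 0.5
        x = sample_truncated_normal(np.zeros(1000), 1.0, lo, hi, rng)
        assert np.all(x >= lo) and np.all(x <= hi)

    def test_extreme_tail_no_clamping(self, rng):
        # interval 10 sigma out in the right tail
        x = sample_truncated_normal(np.zeros(100), 1.0, np.full(100, 10.0), np.full(100, 11.0), rng)
        assert np.all((x >= 10.0) & (x <= 11.0))
        assert np.all(np.isfinite(x))
        assert x.std() > 0  # genuinely random, not clamped to a bound


def _mcar_dataset(n=60, seed=3, **kw):
    cfg = SimConfig(
        n_participants=n,
        seed=seed,
        p_missing=kw.pop("p_missing", 0.2),
        wear_beta=kw.pop("wear_beta", (14, 3)),
        temp_coef=0,
        rain_coef=0,
        sun_coef=0,
        daylength_coef=0,
        n_regions=3,
        **kw,
    )
    return simulate_trial(cfg)


class TestChainedImpute:
    def test_no_missing_yields_identical_copies(self):
        ds, _ = _mcar_dataset(n=12, p_missing=0.0)
        spec = ImputationSpec(m=3, cycles=2, seed=1, pool_arms=True, use_auxiliaries=False)
        out = chained_impute(ds, spec)
        tables = [g.drop(columns="imp").reset_index(drop=True) for _, g in out.data.groupby("imp")]
        for t in tables[1:]:
            pd.testing.assert_frame_equal(t, tables[0])
        # values equal the observed inputs
        merged = tables[0].merge(
            ds.days, on=["participant_id", "year", "day_of_week"], how="left"
        )
        assert np.allclose(merged["log_steps"], np.log(merged["step_count"] + 1))

    def test_fixed_seed_reproducible(self):
        ds, _ = _mcar_dataset(n=40, seed=4)
        spec = ImputationSpec(m=2, cycles=2, seed=9, pool_arms=True, use_auxiliaries=False)
        a = chained_impute(ds, spec)
        b = chained_impute(ds, spec)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_bounds_respected_and_observed_untouched(self):
        ds, _ = _mcar_dataset(n=60, seed=5, p_missing=0.2, wear_beta=(2.2, 2.0))
        spec = ImputationSpec(m=3, cycles=2, seed=2, pool_arms=True, use_auxiliaries=False)
        out = chained_impute(ds, spec)
        merged = out.data.merge(out.bounds, on=["participant_id", "year", "day_of_week"])
        assert (merged["log_steps"] >= merged["lower"] - 1e-9).all()
        assert (merged["log_steps"] <= merged["upper"] + 1e-9).all()
        obs = merged[merged["status"] == STATUS_OBSERVED]
        per_cell = obs.groupby(["participant_id", "year", "day_of_week"])["log_steps"].nunique()
        assert (per_cell == 1).all()

    def test_mcar_imputations_centered_on_truth(self):
        """Mean of imputed log counts for masked cells tracks the withheld truth."""
        ds, truth = _mcar_dataset(n=150, seed=11, p_missing=0.2)
        spec = ImputationSpec(m=4, cycles=3, seed=3, pool_arms=True, use_auxiliaries=False)
        out = chained_impute(ds, spec)
        mask = truth.complete_days.query("week == 1 and status == 'missing'")[
            ["participant_id", "year", "day_of_week", "log_full"]
        ]
        imp = out.data.merge(mask, on=["participant_id", "year", "day_of_week"])
        diff = imp["log_steps"] - np.log(np.exp(imp["log_full"]) + 1)
        se = diff.std(ddof=1) / np.sqrt(imp.groupby(
            ["participant_id", "year", "day_of_week"]
        ).ngroups)
        assert abs(diff.mean()) < 3 * se

    def test_small_arm_errors_suggest_pooling(self):
        ds, _ = _mcar_dataset(n=20, seed=6)
        spec = ImputationSpec(m=2, cycles=1, seed=1, pool_arms=False, use_auxiliaries=False)
        with pytest.raises(MalformedInputError, match="pool_arms"):
            chained_impute(ds, spec)

    def test_missing_cells_in_grid_rejected(self):
        ds, _ = _mcar_dataset(n=12, p_missing=0.0)
        ds.days = ds.days.iloc[:-1]
        spec = ImputationSpec(m=2, cycles=1, seed=1, pool_arms=True, use_auxiliaries=False)
        with pytest.raises(MalformedInputError, match="cells absent"):
            chained_impute(ds, spec)

    def test_spec_validation(self):
        with pytest.raises(ParameterError):
            ImputationSpec(m=1).validate()
        with pytest.raises(ParameterError):
            ImputationSpec(cycles=0).validate()
        with pytest.raises(ParameterError):
            ImputationSpec(param_draw="magic").validate()


def test_single_column_draws_match_bayesian_oracle():
    """With one incomplete column and everything else exact, one cycle of
    chained imputation is Bayesian-linear-regression posterior-predictive
    sampling; compare distributions by KS against an independent oracle."""
    rng = np.random.default_rng(21)
    n = 400
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    beta = np.array([1.0, 0.5])
    sigma = 0.7
    y = X @ beta + rng.normal(0, sigma, n)
    miss = np.zeros(n, dtype=bool)
    miss[:80] = True
    lower = np.where(miss, -np.inf, y)
    upper = np.where(miss, np.inf, y)
    fit = fit_interval_regression(X, lower, upper)

    draws = []
    for _ in range(200):
        draws.append(
            draw_imputations(fit, X[miss], lower[miss], upper[miss], rng)
        )
    ours = np.concatenate(draws)

    # oracle: classical normal-linear posterior predictive on the complete rows
    Xc, yc = X[~miss], y[~miss]
    XtX_inv = np.linalg.inv(Xc.T @ Xc)
    bhat = XtX_inv @ Xc.T @ yc
    resid = yc - Xc @ bhat
    s2 = resid @ resid / (len(yc) - 2)
    oracle = []
    for _ in range(200):
        s2_draw = s2 * (len(yc) - 2) / rng.chisquare(len(yc) - 2)
        b_draw = rng.multivariate_normal(bhat, s2_draw * XtX_inv)
        oracle.append(X[miss] @ b_draw + rng.normal(0, np.sqrt(s2_draw), miss.sum()))
    oracle = np.concatenate(oracle)

    ks = stats.ks_2samp(ours, oracle)
    assert ks.pvalue > 0.001


def test_more_predictors_reduce_between_imputation_variance():
    """Adding 7 informative predictors lowers between-imputation variance of
    the imputed values (paired, one-sided)."""
    rng = np.random.default_rng(31)
    n = 300
    Z = rng.normal(size=(n, 7))
    latent = Z.sum(axis=1) * 0.3
    y = 1.0 + latent + rng.normal(0, 0.5, n)
    miss = np.zeros(n, dtype=bool)
    miss[:60] = True
    lower = np.where(miss, -np.inf, y)
    upper = np.where(miss, np.inf, y)

    X_small = np.column_stack([np.ones(n)])
    X_big = np.column_stack([np.ones(n), Z])

    def between_var(X):
        fit = fit_interval_regression(X, lower, upper)
        r = np.random.default_rng(99)
        draws = np.array(
            [draw_imputations(fit, X[miss], lower[miss], upper[miss], r) for _ in range(20)]
        )
        return draws.var(axis=0, ddof=1).mean()

    assert between_var(X_big) < between_var(X_small)
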