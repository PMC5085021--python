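import math
import warnings

import numpy as np
import pytest
from scipy.optimize import minimize

from ecgc import PenaltyConfig, aic_score, build_lagged_design, elastic_net_fit, fit_path
from ecgc.copula import TimeSeriesMatrix

from conftest import standardized_design


def split_qp_oracle(X, y, lam, alpha):
    """Independent solver: the elastic net as a smooth bound-constrained QP.

    Writing beta = b+ - b- with b+, b- >= 0 makes the l1 term linear, so the
    whole objective is smooth and L-BFGS-B applies.
    """
    n, m = X.shape

    def obj(z):
        beta = z[:m] - z[m:]
        r = y - X @ beta
        return (r @ r) / (2 * n) + lam * (
            alpha * z.sum() + (1 - alpha) / 2 * (beta @ beta)
        )

    res = minimize(
        obj,
        np.zeros(2 * m),
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * m),
        options={"ftol": 1e-16, "gtol": 1e-12, "maxiter": 50_000},
    )
    return res.x[:m] - res.x[m:]


class TestElasticNetFit:
    def test_lambda_zero_is_ols(self, rng):
        X = standardized_design(rng, 30, 5)
        y = rng.standard_normal(30)
        y -= y.mean()
        beta = elastic_net_fit(X, y, 0.0, 1.0, tol=1e-12)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(beta, ols, atol=1e-8)

    def test_lambda_max_zeroes_everything(self, rng):
        X = standardized_design(rng, 40, 6)
        y = rng.standard_normal(40)
        y -= y.mean()
        for alpha in (0.3, 1.0):
            lam_max = np.max(np.abs(X.T @ y)) / (len(y) * alpha)
            beta = elastic_net_fit(X, y, lam_max * 1.0001, alpha)
            assert np.all(beta == 0.0)

    def test_orthonormal_closed_form(self, rng):
        # XtX / n = I: each coordinate is soft-thresholded independently
        n, m = 64, 8
        Q, _ = np.linalg.qr(rng.standard_normal((n, m)))
        X = Q * math.sqrt(n)
        y = rng.standard_normal(n)
        b = X.T @ y / n
        for lam, alpha in [(0.05, 1.0), (0.2, 0.5), (0.1, 0.2)]:
            beta = elastic_net_fit(X, y, lam, alpha, tol=1e-12)
            expected = np.sign(b) * np.maximum(np.abs(b) - lam * alpha, 0.0)
            expected /= 1.0 + lam * (1 - alpha)
            np.testing.assert_allclose(beta, expected, atol=1e-9)

    def test_matches_generic_convex_oracle(self, rng):
        worst = 0.0
        for _ in range(8):
            X = standardized_design(rng, 20, 10)
            y = X[:, :3] @ np.array([1.0, -2.0, 0.5]) + rng.standard_normal(20)
            y -= y.mean()
            lam = rng.uniform(0.01, 0.5)
            alpha = rng.uniform(0.1, 1.0)
            beta = elastic_net_fit(X, y, lam, alpha, tol=1e-11)
            oracle = split_qp_oracle(X, y, lam, alpha)
            worst = max(worst, float(np.max(np.abs(beta - oracle))))
        assert worst <= 1e-5

    def test_matches_reference_library(self, rng):
        sklearn = pytest.importorskip("sklearn.linear_model")
        X = standardized_design(rng, 50, 8)
        y = X[:, 0] * 2 - X[:, 4] + rng.standard_normal(50)
        y -= y.mean()
        for lam, alpha in [(0.1, 1.0), (0.3, 0.4)]:
            ref = sklearn.ElasticNet(
                alpha=lam, l1_ratio=alpha, fit_intercept=False,
                tol=1e-12, max_iter=200_000,
            ).fit(X, y)
            beta = elastic_net_fit(X, y, lam, alpha, tol=1e-12)
            np.testing.assert_allclose(beta, ref.coef_, atol=1e-7)

    def test_ridge_limit_is_dense_and_shrunk(self, rng):
        X = standardized_design(rng, 100, 5)
        y = X @ np.array([1.0, 0.8, -0.6, 0.5, -0.4]) + 0.1 * rng.standard_normal(100)
        y -= y.mean()
        beta = elastic_net_fit(X, y, 0.5, 0.01)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.all(beta != 0.0)  # near-ridge keeps every coefficient
        assert np.all(np.abs(beta) < np.abs(ols))  # ... shrunk toward zero

    @pytest.mark.parametrize("bad", [-0.1])
    def test_negative_lambda_rejected(self, bad, rng):
        X = standardized_design(rng, 10, 2)
        with pytest.raises(ValueError):
            elastic_net_fit(X, np.zeros(10), bad, 1.0)

    def test_non_finite_rejected(self, rng):
        X = standardized_design(rng, 10, 2)
        y = np.zeros(10)
        y[0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            elastic_net_fit(X, y, 0.1, 1.0)


class TestAicScore:
    def test_monotone_in_df_at_fixed_rss(self):
        assert aic_score(5.0, 1, 50) < aic_score(5.0, 2, 50)

    def test_closed_form_zero(self):
        assert aic_score(50.0, 0, 50) == pytest.approx(0.0)

    def test_rss_df_tradeoff(self):
        # moving from (rss=10, df=2) to (rss=9, df=5) buys 50 ln(10/9) ~ 5.27
        # in fit but costs 2*3 = 6 in penalty, so the sparser model wins
        sparse = aic_score(10.0, 2, 50)
        dense = aic_score(9.0, 5, 50)
        assert sparse < dense
        assert 50 * math.log(10 / 9) == pytest.approx(5.268, abs=1e-3)

    def test_zero_rss_guard(self):
        assert math.isfinite(aic_score(0.0, 3, 20))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            aic_score(-1.0, 0, 10)
        with pytest.raises(ValueError):
            aic_score(1.0, 0, 0)


def _design_from(values, target, L):
    X = TimeSeriesMatrix(values, names=tuple(f"v{i}" for i in range(values.shape[1])))
    return build_lagged_design(X, target, L)


class TestFitPath:
    def test_pure_noise_selects_near_empty_model(self):
        dfs = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            values = r.standard_normal((205, 5))
            fit = fit_path(_design_from(values, 0, 1))
            dfs.append(fit.df)
        assert np.median(dfs) <= 1

    def test_strong_predictor_always_selected(self):
        hits = 0
        reps = 40
        for seed in range(reps):
            r = np.random.default_rng(1000 + seed)
            x = r.standard_normal(201)
            y = np.empty(201)
            y[0] = r.standard_normal()
            y[1:] = 0.9 * x[:-1] + 0.1 * r.standard_normal(200)
            values = np.column_stack([y, x])
            design = _design_from(values, 0, 1)
            fit = fit_path(design, PenaltyConfig())
            k = design.column_map.index((1, 1))
            hits += abs(fit.coefficients[k]) > 1e-8
        assert hits >= 0.95 * reps

    def test_lasso_grid_restricts_alpha(self, rng):
        values = rng.standard_normal((50, 3))
        fit = fit_path(_design_from(values, 0, 2), PenaltyConfig(alpha_grid=(1.0,)))
        assert fit.alpha == 1.0

    def test_df_counts_nonzeros_and_rss_nonnegative(self, rng):
        values = rng.standard_normal((80, 4))
        fit = fit_path(_design_from(values, 1, 2))
        assert fit.df == int(np.sum(np.abs(fit.coefficients) > 1e-8))
        assert fit.rss >= 0.0

    def test_zero_variance_column_dropped_with_warning(self, rng):
        values = rng.standard_normal((40, 2))
        values[:, 1] = 3.14  # constant series -> all its lag columns constant
        design = _design_from(values, 0, 1)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            fit = fit_path(design)
        k = design.column_map.index((1, 1))
        assert fit.coefficients[k] == 0.0

    def test_df_shrinks_with_lambda_on_average(self, rng):
        # along a fixed-alpha path, stronger penalty should not add terms
        increases = 0
        trials = 20
        for _ in range(trials):
            X = standardized_design(rng, 60, 8)
            y = X[:, 0] + rng.standard_normal(60)
            y -= y.mean()
            lam_max = np.max(np.abs(X.T @ y)) / 60
            dfs = [
                int(np.sum(np.abs(elastic_net_fit(X, y, lam, 1.0)) > 1e-8))
                for lam in np.geomspace(lam_max, 0.01 * lam_max, 10)
            ]
            increases += sum(a > b for a, b in zip(dfs, dfs[1:]))
        assert increases <= trials  # strictly monotone on average, rare blips allowed


class TestPenaltyConfig:
    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            PenaltyConfig(alpha_grid=(0.0, 0.5))
        with pytest.raises(ValueError):
            PenaltyConfig(alpha_grid=())

    def test_default_grid_is_tenths(self):
        assert PenaltyConfig().alpha_grid == tuple(
            pytest.approx(0.1 * k) for k in range(1, 11)
        )
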