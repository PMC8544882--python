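"""Standardization, PCA, lognormal/gamma regression, model comparison, diagnostics."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import optimize, stats

from coralith.errors import DomainError, FitError
from coralith.pcreg import (
    _fit_gamma_design,
    compare_distributions,
    fit_gamma_glm,
    fit_lognormal_regression,
    pca,
    pseudo_r2,
    simulate_residual_diagnostics,
    standardize,
)


def morph_frame(rng, n=50, p=5):
    return pd.DataFrame(
        rng.standard_normal((n, p)) * rng.uniform(0.5, 3.0, p) + rng.uniform(-2, 5, p),
        columns=[f"v{j}" for j in range(p)],
    )


class TestStandardize:
    def test_unit_column(self):
        std = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(std.X[:, 0], [-1, 0, 1])

    def test_columns_have_zero_mean_unit_sd(self, rng):
        std = standardize(morph_frame(rng))
        np.testing.assert_allclose(std.X.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(std.X.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_back_transform_round_trip(self, rng):
        df = morph_frame(rng, n=20)
        std = standardize(df)
        np.testing.assert_allclose(std.back_transform(), df.to_numpy(), rtol=1e-12)

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "flat": [2.0, 2.0, 2.0]})
        with pytest.raises(DomainError, match="flat"):
            standardize(df)


class TestPCA:
    def test_perfectly_correlated_pair(self, rng):
        x = rng.standard_normal(30)
        std = standardize(pd.DataFrame({"a": x, "b": 3 * x + 1}))
        pc = pca(std)
        assert pc.variance_fraction[0] == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(pc.loadings[:, 0], [0.70711, 0.70711], atol=1e-5)

    def test_single_column(self, rng):
        pc = pca(standardize(pd.DataFrame({"a": rng.standard_normal(10)})))
        assert pc.variance_fraction[0] == pytest.approx(1.0)
        assert pc.loadings[0, 0] == pytest.approx(1.0)

    def test_independent_columns_share_variance(self):
        rng = np.random.default_rng(5)
        pc = pca(standardize(morph_frame(rng, n=10_000)))
        np.testing.assert_allclose(pc.variance_fraction, 0.2, atol=0.03)

    def test_reconstruction(self, rng):
        std = standardize(morph_frame(rng))
        pc = pca(std)
        np.testing.assert_allclose(pc.scores @ pc.loadings.T, std.X, atol=1e-10)
        np.testing.assert_allclose(pc.loadings.T @ pc.loadings, np.eye(5), atol=1e-10)
        assert pc.variance_fraction.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(pc.eigenvalues) <= 1e-12)

    def test_row_permutation_leaves_loadings_unchanged(self, rng):
        df = morph_frame(rng)
        pc1 = pca(standardize(df))
        pc2 = pca(standardize(df.sample(frac=1.0, random_state=3)))
        np.testing.assert_allclose(pc1.loadings, pc2.loadings, atol=1e-12)

    def test_sign_convention(self, rng):
        pc = pca(standardize(morph_frame(rng)))
        for j in range(5):
            col = pc.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0


class TestLognormalRegression:
    def test_exact_exponential_relationship(self, rng):
        s = rng.standard_normal((20, 2))
        y = np.exp(s[:, 0])
        fit = fit_lognormal_regression(y, s)
        assert fit.coefficients[1] == pytest.approx(1.0, abs=1e-10)
        assert fit.pseudo_r2 == pytest.approx(1.0, abs=1e-10)

    def test_normal_equations_oracle(self, rng):
        s = rng.standard_normal((6, 2))
        y = np.exp(1.0 + 0.5 * s[:, 0] - 0.3 * s[:, 1] + 0.2 * rng.standard_normal(6))
        fit = fit_lognormal_regression(y, s)
        X = np.column_stack([np.ones(6), s])
        beta = np.linalg.solve(X.T @ X, X.T @ np.log(y))
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-9)

    def test_nonpositive_response_rejected(self, rng):
        s = rng.standard_normal((10, 2))
        with pytest.raises(DomainError):
            fit_lognormal_regression(np.r_[np.ones(9), 0.0], s)

    def test_null_slope_confidence_coverage(self):
        """With no planted effect the nominal 95% CI covers zero ~95% of the time."""
        rng = np.random.default_rng(31)
        cover = 0
        n_reps = 200
        for _ in range(n_reps):
            s = rng.standard_normal((30, 2))
            y = np.exp(1.0 + 0.4 * rng.standard_normal(30))
            fit = fit_lognormal_regression(y, s)
            crit = stats.t.ppf(0.975, 30 - 3)
            lo = fit.coefficients[1] - crit * fit.se[1]
            hi = fit.coefficients[1] + crit * fit.se[1]
            cover += lo <= 0.0 <= hi
        assert cover / n_reps >= 0.93


class TestGammaGLM:
    def test_intercept_only_mle_is_log_mean(self):
        y = np.array([1.0, 2.0, 4.0])
        fit = _fit_gamma_design(y, np.ones((3, 1)), ["b0"])
        assert fit.coefficients[0] == pytest.approx(np.log(7 / 3), abs=1e-8)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(8)
        s = rng.standard_normal((500, 2))
        mu = np.exp(1.0 + 0.5 * s[:, 0] - 0.3 * s[:, 1])
        y = rng.gamma(5.0, mu / 5.0)
        fit = fit_gamma_glm(y, s)
        np.testing.assert_allclose(fit.coefficients, [1.0, 0.5, -0.3], atol=0.1)
        assert fit.phi == pytest.approx(1 / 5.0, abs=0.06)
        assert fit.converged

    def test_shape_dispersion_identity(self, rng):
        s = rng.standard_normal((40, 2))
        y = rng.gamma(4.0, np.exp(0.5 + 0.3 * s[:, 0]) / 4.0)
        fit = fit_gamma_glm(y, s)
        assert fit.alpha_shape == 1.0 / fit.phi  # definitional
        assert fit.alpha_shape * fit.phi == pytest.approx(1.0, rel=1e-15)
        np.testing.assert_allclose(fit.rate_hat * fit.mu_hat, fit.alpha_shape, rtol=1e-12)

    def test_matches_statsmodels_glm(self):
        """IRLS agrees with an independently fitted gamma GLM on 20 datasets."""
        for r in range(20):
            rng = np.random.default_rng(100 + r)
            s = rng.standard_normal((40, 2))
            mu = np.exp(0.8 + 0.4 * s[:, 0] + 0.2 * s[:, 1])
            y = rng.gamma(3.0, mu / 3.0)
            fit = fit_gamma_glm(y, s)
            X = np.column_stack([np.ones(40), s])
            ref = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log())).fit()
            np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)
            assert fit.phi == pytest.approx(ref.pearson_chi2 / ref.df_resid, rel=1e-6)

    def test_matches_generic_ml_optimizer(self):
        """For the log-link gamma, the coefficient MLE is independent of the
        shape, so minimizing sum(log mu + y/mu) is an independent oracle."""
        for r in range(5):
            rng = np.random.default_rng(300 + r)
            s = rng.standard_normal((40, 2))
            y = rng.gamma(5.0, np.exp(1.0 + 0.5 * s[:, 0]) / 5.0)
            fit = fit_gamma_glm(y, s)
            X = np.column_stack([np.ones(40), s])

            def nll(beta):
                mu = np.exp(X @ beta)
                return np.sum(np.log(mu) + y / mu)

            res = optimize.minimize(nll, np.zeros(3), method="BFGS", tol=1e-12)
            np.testing.assert_allclose(fit.coefficients, res.x, atol=1e-6)


class TestPseudoR2:
    @pytest.mark.parametrize(("d", "nd", "r2"), [(8, 8, 0.0), (0, 8, 1.0), (2, 8, 0.75)])
    def test_examples(self, d, nd, r2):
        assert pseudo_r2(d, nd) == pytest.approx(r2)

    def test_invalid_null_deviance(self):
        with pytest.raises(DomainError):
            pseudo_r2(1.0, 0.0)

    def test_monotone_in_deviance(self):
        values = [pseudo_r2(d, 10.0) for d in np.linspace(0, 10, 11)]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestCompareDistributions:
    def test_lognormal_sample_selects_lognormal(self):
        rng = np.random.default_rng(2)
        y = rng.lognormal(1.0, 1.0, 2000)
        tab = compare_distributions(y)
        assert tab.loc[tab["best"], "family"].iloc[0] == "lognormal"

    def test_truncated_normal_sample_selects_normal(self):
        rng = np.random.default_rng(3)
        y = rng.normal(10.0, 1.0, 2500)
        y = y[y > 0][:2000]
        tab = compare_distributions(y)
        assert tab.loc[tab["best"], "family"].iloc[0] == "normal"

    def test_gamma_sample_selects_gamma(self):
        rng = np.random.default_rng(4)
        y = rng.gamma(2.0, 3.0, 2000)
        tab = compare_distributions(y)
        assert tab.loc[tab["best"], "family"].iloc[0] == "gamma"

    def test_too_small_sample_errors(self):
        with pytest.raises(DomainError):
            compare_distributions([1.0, 2.0, 3.0])

    def test_nonpositive_values_fall_back_to_normal_only(self):
        rng = np.random.default_rng(5)
        with pytest.warns(UserWarning, match="non-positive"):
            tab = compare_distributions(np.r_[rng.normal(0, 1, 50)])
        assert list(tab["family"]) == ["normal"]


def _gamma_fit(rng, n=50, shape=5.0):
    s = rng.standard_normal((n, 2))
    mu = np.exp(1.0 + 0.3 * s[:, 0] - 0.2 * s[:, 1])
    y = rng.gamma(shape, mu / shape)
    return fit_gamma_glm(y, s)


class TestDiagnostics:
    def test_deterministic_given_seed(self, rng):
        fit = _gamma_fit(rng)
        assert simulate_residual_diagnostics(fit, 120, seed=7) == simulate_residual_diagnostics(
            fit, 120, seed=7
        )

    def test_simulation_count_limits(self, rng):
        fit = _gamma_fit(rng)
        with pytest.raises(DomainError):
            simulate_residual_diagnostics(fit, 10, seed=0)
        with pytest.warns(UserWarning, match="coarse"):
            simulate_residual_diagnostics(fit, 50, seed=0)

    def test_unconverged_fit_rejected(self, rng):
        fit = _gamma_fit(rng)
        fit.converged = False
        with pytest.raises(FitError):
            simulate_residual_diagnostics(fit, 100, seed=0)

    def test_dispersion_type_one_error_is_bounded(self):
        """Well-specified gamma data rarely trips the dispersion alarm."""
        rej = 0
        n_reps = 500
        for r in range(n_reps):
            fit = _gamma_fit(np.random.default_rng(40_000 + r))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rej += simulate_residual_diagnostics(fit, 100, seed=r).dispersion_p < 0.05
        assert rej / n_reps <= 0.08

    def test_dispersion_power_against_variance_inflation(self):
        """Responses with 4x the fitted gamma variance are usually detected."""
        rej = 0
        n_reps = 200
        for r in range(n_reps):
            rng = np.random.default_rng(60_000 + r)
            fit = _gamma_fit(rng, n=200)
            shape_bad = fit.alpha_shape / 4.0  # same mean, 4x variance
            y_bad = rng.gamma(shape_bad, fit.mu_hat / shape_bad)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = simulate_residual_diagnostics(fit, 100, seed=r, y=y_bad).dispersion_p
            rej += p < 0.05
        assert rej / n_reps >= 0.50
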