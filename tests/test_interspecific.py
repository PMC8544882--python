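"""One-way ANOVA, Tukey contrasts, Breusch-Pagan, Cook's-distance screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from coralith.errors import DegenerateFitError, DomainError
from coralith.interspecific import (
    anova_outlier_report,
    breusch_pagan,
    cooks_outliers,
    fit_oneway_anova,
    summarize_median_mad,
    tukey_contrasts,
)
from coralith.pcreg import fit_lognormal_regression


def grouped(values_by_group):
    rows = [
        {"specimen_id": f"{g}{i}", "species": g, "value": v}
        for g, vals in values_by_group.items()
        for i, v in enumerate(vals)
    ]
    return pd.DataFrame(rows)


def lognormal_groups(rng, k=5, n=10, mu=1.0, sigma=0.5, shift=None):
    groups = {}
    for j in range(k):
        m = mu if shift is None else mu + shift[j]
        groups[f"g{j}"] = np.exp(m + sigma * rng.standard_normal(n))
    return grouped(groups)


class TestMedianMad:
    @pytest.mark.parametrize(
        ("vals", "const", "expected"),
        [([1, 2, 3], 1.0, (2, 1)), ([1, 2, 3], 1.4826, (2, 1.4826)),
         ([5, 5, 5, 5], 1.4826, (5, 0))],
    )
    def test_examples(self, vals, const, expected):
        med, mad = summarize_median_mad(vals, const)
        assert (med, mad) == (pytest.approx(expected[0]), pytest.approx(expected[1]))

    def test_empty_errors(self):
        with pytest.raises(DomainError):
            summarize_median_mad([])


class TestOneWayAnova:
    def test_five_by_ten_degrees_of_freedom(self, rng):
        fit = fit_oneway_anova(lognormal_groups(rng))
        assert fit.df_residual == 45
        assert fit.df_between == 4
        assert fit.n == 50 and fit.k == 5

    def test_two_group_f_equals_t_squared(self, rng):
        df = lognormal_groups(rng, k=2, n=8)
        fit = fit_oneway_anova(df, log_transform=True)
        a = np.log(df[df.species == "g0"]["value"])
        b = np.log(df[df.species == "g1"]["value"])
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        assert fit.F == pytest.approx(t**2, rel=1e-9)

    def test_identical_values_degenerate(self):
        df = grouped({"a": [3.0] * 5, "b": [3.0] * 5})
        with pytest.raises(DegenerateFitError):
            fit_oneway_anova(df, log_transform=False)

    def test_zeros_under_log_refused_then_offset_policy(self):
        df = grouped({"a": [0.0, 1.0, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(DomainError, match="zero"):
            fit_oneway_anova(df, log_transform=True)
        fit = fit_oneway_anova(df, log_transform=True, zero_policy="half_min_offset")
        assert fit.n == 6  # zero replaced by half the minimum positive value, not dropped

    def test_relabeling_and_shift_invariance(self, rng):
        df = lognormal_groups(rng)
        f1 = fit_oneway_anova(df)
        relabeled = df.assign(species=df["species"].map(lambda s: "zz" + s))
        f2 = fit_oneway_anova(relabeled)
        shifted = df.assign(value=df["value"] * np.e)  # constant shift on the log scale
        f3 = fit_oneway_anova(shifted)
        assert f2.F == pytest.approx(f1.F, rel=1e-10)
        assert f3.F == pytest.approx(f1.F, rel=1e-10)

    def test_null_rejection_rate_is_nominal(self):
        """Equal lognormal groups: log-scale ANOVA rejects at ~alpha=0.05."""
        rng = np.random.default_rng(2024)
        rej = 0
        n_reps = 2000
        for _ in range(n_reps):
            y = rng.lognormal(1.0, 0.6, 50)
            labels = np.repeat([f"g{j}" for j in range(5)], 10)
            df = pd.DataFrame({"species": labels, "value": y})
            fit = fit_oneway_anova(df)
            rej += fit.p_F < 0.05
        assert 0.03 <= rej / n_reps <= 0.07


class TestTukey:
    def test_contrast_count_for_five_groups(self, rng):
        fit = fit_oneway_anova(lognormal_groups(rng))
        assert len(tukey_contrasts(fit)) == 10

    def test_two_groups_collapse_to_pooled_t_test(self, rng):
        df = lognormal_groups(rng, k=2, n=10)
        fit = fit_oneway_anova(df)
        (con,) = tukey_contrasts(fit)
        a = np.log(df[df.species == "g0"]["value"])
        b = np.log(df[df.species == "g1"]["value"])
        _, p = stats.ttest_ind(a, b, equal_var=True)
        assert con.p_adj == pytest.approx(p, abs=1e-6)

    def test_identical_group_means_give_unit_p(self):
        base = [1.0, 2.0, 3.0, 4.0]
        df = grouped({"a": base, "b": base, "c": base})
        fit = fit_oneway_anova(df, log_transform=False)
        for con in tukey_contrasts(fit):
            assert con.t == pytest.approx(0.0, abs=1e-12)
            assert con.p_adj == pytest.approx(1.0)

    def test_matches_statsmodels_tukeyhsd(self, rng):
        df = lognormal_groups(rng, k=4, n=6, shift=[0, 0.3, -0.2, 0.8])
        fit = fit_oneway_anova(df)
        ours = {c.pair: c.p_adj for c in tukey_contrasts(fit)}
        sm_res = pairwise_tukeyhsd(np.log(df["value"].to_numpy()), df["species"].to_numpy())
        for row, p_sm in zip(sm_res._results_table.data[1:], sm_res.pvalues):
            g1, g2 = str(row[0]), str(row[1])
            assert ours[(g1, g2)] == pytest.approx(p_sm, abs=1e-6)

    def test_adjustment_is_conservative(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            df = lognormal_groups(rng, k=4, n=5, shift=rng.normal(0, 0.5, 4))
            fit = fit_oneway_anova(df)
            for con in tukey_contrasts(fit):
                p_raw = 2 * stats.t.sf(abs(con.t), con.df_residual)
                assert con.p_adj >= p_raw - 1e-12


class TestBreuschPagan:
    def test_constant_squared_residuals_give_zero_statistic(self):
        # residuals are +/-1 everywhere -> squared residuals constant -> R^2 = 0
        df = grouped({"a": [0.0, 2.0, 0.0, 2.0], "b": [5.0, 7.0, 5.0, 7.0]})
        fit = fit_oneway_anova(df, log_transform=False)
        lm, dof, p = breusch_pagan(fit)
        assert lm == pytest.approx(0.0, abs=1e-10)
        assert dof == 1
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_auxiliary_regression(self, rng):
        df = lognormal_groups(rng, k=3, n=4, sigma=0.8)
        fit = fit_oneway_anova(df)
        lm, dof, p = breusch_pagan(fit)
        # independent two-step oracle: regress e^2 on group dummies, LM = n R^2
        e2 = fit.residuals**2
        X = np.column_stack(
            [np.ones(fit.n)] + [(fit.labels == g).astype(float) for g in fit.groups[1:]]
        )
        beta = np.linalg.lstsq(X, e2, rcond=None)[0]
        ss_res = np.sum((e2 - X @ beta) ** 2)
        ss_tot = np.sum((e2 - e2.mean()) ** 2)
        lm_oracle = fit.n * (1 - ss_res / ss_tot)
        assert lm == pytest.approx(lm_oracle, abs=1e-9)
        assert dof == 2
        assert p == pytest.approx(stats.chi2.sf(lm_oracle, 2), abs=1e-9)

    def test_type_one_error_under_homoscedasticity(self):
        rng = np.random.default_rng(9)
        rej = 0
        n_reps = 2000
        labels = np.repeat([f"g{j}" for j in range(5)], 10)
        for _ in range(n_reps):
            df = pd.DataFrame({"species": labels, "value": rng.standard_normal(50)})
            fit = fit_oneway_anova(df, log_transform=False)
            rej += breusch_pagan(fit)[2] < 0.05
        assert 0.03 <= rej / n_reps <= 0.07


class TestCooks:
    def test_threshold_is_four_over_n(self, rng):
        fit = fit_oneway_anova(lognormal_groups(rng))
        report = cooks_outliers(fit)
        assert report.threshold == pytest.approx(4.0 / 50) == pytest.approx(0.08)

    def test_matches_leave_one_out_refits(self, rng):
        """Closed-form Cook's D equals explicit LOO refitting on a small regression."""
        n = 8
        s = rng.standard_normal((n, 2))
        y = np.exp(0.5 + 0.8 * s[:, 0] + 0.2 * rng.standard_normal(n))
        fit = fit_lognormal_regression(y, s)
        report = cooks_outliers(fit)
        X, z = fit.X, np.log(y)
        beta = np.linalg.lstsq(X, z, rcond=None)[0]
        p = X.shape[1]
        s2 = np.sum((z - X @ beta) ** 2) / (n - p)
        for i in range(n):
            keep = np.arange(n) != i
            beta_i = np.linalg.lstsq(X[keep], z[keep], rcond=None)[0]
            diff = X @ beta - X @ beta_i
            d_oracle = np.sum(diff**2) / (p * s2)
            assert report.cooks_d.iloc[i] == pytest.approx(d_oracle, abs=1e-9)

    def test_displaced_point_is_most_influential(self):
        df = grouped({"a": [2.0, 2.0, 2.0, 2.0, 9.0], "b": [5.0, 5.0, 5.0, 5.0, 5.01]})
        report = anova_outlier_report(df, log_transform=False)
        assert report.cooks_d.idxmax() == "a4"

    def test_refit_excludes_flagged_points(self, rng):
        df = lognormal_groups(rng, k=3, n=8)
        df.loc[0, "value"] = 1e4  # gross outlier
        report = anova_outlier_report(df)
        assert any(sid == df.loc[0, "specimen_id"] for sid, _ in report.flagged)
        assert report.refit is not None
        assert report.refit.n == 24 - len(report.flagged)
        assert {"full", "outliers_excluded"} <= set(report.comparison["model"])
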