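"""Cohort statistics: ANOVA oracle, chi-square, McNemar, logistic fits."""

import numpy as np
import pandas as pd
import pytest

from breathnet.stats import (chi_square_vs_control, correlation_matrix,
                             logistic_symptom_regression, mcnemar_test,
                             rm_anova_gg, sf_ratio, spo2_fio2_regression)

from conftest import stream


def brute_force_rm_anova(X):
    """Sums of squares from their definitions, all loops spelled out."""
    n, k = X.shape
    grand = X.mean()
    col_means = [X[:, j].mean() for j in range(k)]
    row_means = [X[i, :].mean() for i in range(n)]
    ss_effect = sum(n * (cm - grand) ** 2 for cm in col_means)
    ss_subj = sum(k * (rm - grand) ** 2 for rm in row_means)
    ss_total = sum((X[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_error = ss_total - ss_effect - ss_subj
    F = (ss_effect / (k - 1)) / (ss_error / ((n - 1) * (k - 1)))
    eta2p = ss_effect / (ss_effect + ss_error)
    return F, eta2p


class TestRmAnova:
    def test_matches_brute_force_oracle(self):
        for s in range(100):
            rng = stream(101, s)
            n = int(rng.integers(3, 9))
            k = int(rng.integers(2, 6))
            X = rng.normal(size=(n, k))
            res = rm_anova_gg(X)
            F, eta2p = brute_force_rm_anova(X)
            assert res.F == pytest.approx(F, abs=1e-10)
            assert res.eta2p == pytest.approx(eta2p, abs=1e-10)

    def test_agrees_with_pingouin(self):
        """Independent cross-check against pingouin's rm_anova."""
        import pingouin as pg
        rng = stream(102)
        X = rng.normal(size=(10, 4))
        res = rm_anova_gg(X)
        ref = pg.rm_anova(pd.DataFrame(X), effsize="np2")
        assert res.F == pytest.approx(float(ref["F"][0]), rel=1e-9)
        assert res.eta2p == pytest.approx(float(ref["np2"][0]), abs=1e-9)

    def test_identical_columns_give_zero_effect(self):
        X = np.tile(stream(103).normal(size=6)[:, None], (1, 3))
        res = rm_anova_gg(X)
        assert res.F == 0.0 and res.eta2p == 0.0 and res.p == 1.0

    def test_two_levels_trivially_spherical(self):
        res = rm_anova_gg(stream(104).normal(size=(8, 2)))
        assert res.gg_epsilon == 1.0 and not res.corrected
        assert res.mauchly_p == 1.0

    def test_gg_correction_deflates_dfs_when_sphericity_violated(self):
        rng = stream(105)
        base = rng.normal(size=12)
        # second and third columns nearly collinear with the first ->
        # wildly unequal difference variances -> sphericity violated
        X = np.column_stack([base, base + rng.normal(0, 0.01, 12),
                             base + rng.normal(0, 0.01, 12) + 0.5,
                             rng.normal(size=12)])
        res = rm_anova_gg(X)
        assert res.mauchly_p < 0.05 and res.corrected
        assert res.df_effect < X.shape[1] - 1
        assert res.gg_epsilon < 1.0

    def test_incomplete_or_tiny_input_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_gg(np.full((5, 1), 1.0))
        with pytest.raises(ValueError):
            rm_anova_gg(np.zeros((2, 3)))
        X = np.ones((5, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            rm_anova_gg(X)


class TestChiSquare:
    def test_hand_computed_cases(self):
        res = chi_square_vs_control(6, 9, 12)
        assert res.chi2 == pytest.approx(3.0) and res.df == 1

    def test_matching_counts_give_zero(self):
        assert chi_square_vs_control(5, 5, 12).chi2 == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_control_rejected(self):
        with pytest.raises(ValueError, match="exact"):
            chi_square_vs_control(0, 3, 12)
        with pytest.raises(ValueError):
            chi_square_vs_control(5, 13, 12)


class TestMcNemar:
    def test_symmetric_discordance_zero(self):
        pairs = [(True, False)] * 3 + [(False, True)] * 3 + [(True, True)] * 2
        res = mcnemar_test(pairs)
        assert res.chi2 == 0.0

    def test_one_sided_discordance(self):
        pairs = [(True, False)] * 6 + [(False, False)] * 6
        res = mcnemar_test(pairs)
        assert res.chi2 == pytest.approx(6.0)
        assert res.exact_p == pytest.approx(2 * 0.5 ** 6)

    def test_no_discordance_flagged(self):
        res = mcnemar_test([(True, True), (False, False)])
        assert res.chi2 == 0.0 and res.p == 1.0 and "no discordance" in res.note


class TestLogisticRegression:
    def test_constant_predictor_reduces_to_null_model(self):
        y = np.array([0, 1] * 6, dtype=float)
        res = logistic_symptom_regression(np.ones(12), y)
        assert res.r2_mcfadden == 0.0
        assert res.auc == 0.5
        assert res.odds_ratios["x1"] == 1.0

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            logistic_symptom_regression(np.arange(12.0), np.zeros(12))

    def test_perfect_separation_detected(self):
        x = np.arange(12.0)
        y = (x > 5).astype(float)
        with pytest.raises(ValueError, match="separation"):
            logistic_symptom_regression(x, y)

    def test_null_calibration_small_sample(self):
        """Slope-zero data at the study's n = 12: the score-test p is
        approximately uniform, rejecting at 0.05 in 5% +/- 2% of 500
        replicates (both-class, non-separated fits).  The asymptotic LR
        test is anti-conservative at this sample size, which is why the
        report carries the score test alongside it."""
        rej = used = 0
        for i in range(500):
            rng = stream(106, i)
            x = rng.normal(size=12)
            y = (rng.random(12) < 1 / 3).astype(float)
            if len(np.unique(y)) < 2:
                continue
            try:
                res = logistic_symptom_regression(x, y)
            except ValueError:
                continue
            used += 1
            rej += res.score_p < 0.05
        assert rej / used == pytest.approx(0.05, abs=0.02)

    def test_coefficient_coverage_large_sample(self):
        """True beta = 1 at n = 500: the Wald 95% CI covers it in about
        95% of 200 replicates."""
        import statsmodels.api as sm
        cover = 0
        for i in range(200):
            rng = stream(107, i)
            x = rng.normal(size=500)
            y = (rng.random(500) < 1 / (1 + np.exp(-x))).astype(float)
            fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            lo, hi = fit.conf_int()[1]
            cover += lo <= 1.0 <= hi
        assert 0.90 <= cover / 200 <= 0.99

    def test_two_predictor_report_structure(self):
        rng = stream(108)
        X = pd.DataFrame({"rest_te": rng.normal(size=40),
                          "exercise_te": rng.normal(size=40)})
        y = (rng.random(40) < 0.4).astype(float)
        res = logistic_symptom_regression(X, y)
        assert set(res.odds_ratios) == {"rest_te", "exercise_te"}
        assert res.aic == pytest.approx(res.bic, abs=10)  # same ll, k ln n vs 2k
        assert res.vif["rest_te"] >= 1.0 - 1e-9
        for nm, beta in res.coefficients.items():
            assert res.odds_ratios[nm] == pytest.approx(np.exp(beta))


class TestCorrelations:
    def test_column_with_itself(self):
        rng = stream(109)
        df = pd.DataFrame({"a": rng.normal(size=10)})
        df["b"] = df["a"]
        out = correlation_matrix(df)
        assert out["pearson_r"].loc["a", "b"] == pytest.approx(1.0)
        assert out["kendall_tau"].loc["a", "b"] == pytest.approx(1.0)

    def test_kendall_by_enumeration(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4]})
        out = correlation_matrix(df)
        # pairs (1,2)(1,3)(1,4)(2,3)(2,4)(3,4): only (2,3) vs (3,2) is
        # discordant -> C=5, D=1, no ties -> tau = (5-1)/6 = 2/3
        assert out["kendall_tau"].loc["x", "y"] == pytest.approx(2 / 3)

    def test_anti_monotone(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 5], "y": [9.0, 4, 2, 1]})
        out = correlation_matrix(df)
        assert out["pearson_r"].loc["x", "y"] < 0
        assert out["kendall_tau"].loc["x", "y"] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"x": [1.0, 1, 1, 1], "y": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="zero variance"):
            correlation_matrix(df)


class TestSpotMeasures:
    def test_sf_ratio_arithmetic(self):
        assert sf_ratio(100, 1.0) == 100.0
        assert sf_ratio(98, 0.209) == pytest.approx(468.9, abs=0.05)
        assert sf_ratio(90, 0.135) == pytest.approx(666.7, abs=0.05)
        with pytest.raises(ValueError):
            sf_ratio(98, 0.0)

    def test_exact_line_recovered(self):
        x = np.array([13.0, 15.0, 18.0, 21.0])
        y = 1.4 * x + 70
        fit = spo2_fio2_regression(x, y)
        assert fit.slope == pytest.approx(1.4)
        assert fit.intercept == pytest.approx(70.0)
        assert fit.r == pytest.approx(1.0)
        assert fit.sy_x == pytest.approx(0.0, abs=1e-12)

    def test_two_points_exact(self):
        fit = spo2_fio2_regression([13.5, 20.9], [87.0, 98.0])
        assert fit.sy_x == pytest.approx(0.0, abs=1e-12)

    def test_slope_recovery_under_noise(self):
        """Simulated spot measurements (slope 1.416, noise SD 1.7, n=54):
        the slope comes back within +/- 0.3 in at least 90% of 200 runs."""
        ok = 0
        for i in range(200):
            rng = stream(110, i)
            x = np.repeat([13.5, 15.1, 20.9], 18)
            y = 1.416 * x + 68.83 + rng.normal(0, 1.7, size=54)
            ok += abs(spo2_fio2_regression(x, y).slope - 1.416) <= 0.3
        assert ok >= 180

    def test_constant_fio2_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spo2_fio2_regression([15.0, 15.0, 15.0], [90.0, 91.0, 92.0])
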