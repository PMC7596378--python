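"""Clinical outcome statistics: 2x2 tables, logistic models, rank tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from neoqeeg.stats import (ContingencyTable2x2, PerfectSeparationError,
                           RISK_HIGH, RISK_MILD_MODERATE, RISK_NO,
                           classify_ados_risk, collinearity_check,
                           diagnostic_metrics, inverse_transform_dq,
                           linear_model, logistic_fit, mann_whitney_u,
                           odds_ratio, round_half_up, transform_dq)

# the two exposure-outcome tables of the modelled study:
# abnormal first EEG (15/36 vs 4/27) and dysmature background (8/14 vs 11/49)
ABNORMAL_TABLE = ContingencyTable2x2(15, 21, 4, 23)
DYSMATURE_TABLE = ContingencyTable2x2(8, 6, 11, 38)


class TestADOSRisk:
    @pytest.mark.parametrize("score,verbal,category", [
        (0, False, RISK_NO), (9, False, RISK_NO),
        (10, False, RISK_MILD_MODERATE), (13, False, RISK_MILD_MODERATE),
        (14, False, RISK_HIGH),
        (0, True, RISK_NO), (7, True, RISK_NO),
        (8, True, RISK_MILD_MODERATE), (11, True, RISK_MILD_MODERATE),
        (12, True, RISK_HIGH),
    ])
    def test_cutoff_bands(self, score, verbal, category):
        assert classify_ados_risk(score, verbal).category == category

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            classify_ados_risk(-1, True)


class TestOddsRatio:
    def test_abnormal_eeg_table(self):
        res = odds_ratio(ABNORMAL_TABLE)
        assert round_half_up(res.odds_ratio, 1) == 4.1
        assert round_half_up(res.ci_low, 1) == 1.2
        assert round_half_up(res.ci_high, 1) == 14.4

    def test_dysmature_eeg_table(self):
        res = odds_ratio(DYSMATURE_TABLE)
        assert round_half_up(res.odds_ratio, 1) == 4.6
        assert round_half_up(res.ci_low, 1) == 1.3
        assert round_half_up(res.ci_high, 1) == 16.1

    def test_null_table(self):
        res = odds_ratio(ContingencyTable2x2(5, 5, 5, 5))
        assert res.odds_ratio == 1.0
        assert res.ci_low < 1.0 < res.ci_high

    def test_zero_cell_haldane_correction(self):
        res = odds_ratio(ContingencyTable2x2(5, 0, 3, 7))
        assert res.corrected
        assert math.isfinite(res.odds_ratio) and math.isfinite(res.ci_high)

    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)


class TestDiagnosticMetrics:
    def test_abnormal_eeg_percentages(self):
        pct = diagnostic_metrics(ABNORMAL_TABLE).as_percent()
        assert pct == {"sensitivity": 79, "specificity": 52,
                       "ppv": 42, "npv": 85}

    def test_dysmature_eeg_percentages(self):
        pct = diagnostic_metrics(DYSMATURE_TABLE).as_percent()
        assert pct == {"sensitivity": 42, "specificity": 86,
                       "ppv": 57, "npv": 78}

    def test_zero_denominator_flagged_undefined(self):
        m = diagnostic_metrics(ContingencyTable2x2(0, 0, 3, 7))
        assert m.ppv is None
        assert m.npv == 0.7

    def test_counts_recoverable(self):
        t = DYSMATURE_TABLE
        m = diagnostic_metrics(t)
        assert round(m.sensitivity * (t.a + t.c)) == t.a
        assert round(m.ppv * (t.a + t.b)) == t.a

    def test_prevalence_weighted_ppv_identity(self):
        for t in (ABNORMAL_TABLE, DYSMATURE_TABLE,
                  ContingencyTable2x2(3, 9, 2, 11)):
            m = diagnostic_metrics(t)
            prev = (t.a + t.c) / t.total
            ppv = (m.sensitivity * prev
                   / (m.sensitivity * prev + (1 - m.specificity) * (1 - prev)))
            assert abs(ppv - m.ppv) < 1e-12


class TestLogisticFit:
    def test_single_binary_predictor_equals_cross_product_ratio(self):
        t = ABNORMAL_TABLE
        x = np.r_[np.ones(t.a + t.b), np.zeros(t.c + t.d)]
        y = np.r_[np.ones(t.a), np.zeros(t.b), np.ones(t.c), np.zeros(t.d)]
        fit = logistic_fit(pd.DataFrame({"exposed": x}), y)
        want = (t.a * t.d) / (t.b * t.c)
        assert fit.odds_ratio("exposed") == pytest.approx(want, abs=1e-6)
        lo = fit.table.loc["exposed", "ci_low"]
        hi = fit.table.loc["exposed", "ci_high"]
        assert lo < want < hi

    def test_agreement_with_closed_form_on_random_tables(self, rng):
        # MLE of the saturated 2x2 logistic equals the cross-product
        # ratio on every table with all cells >= 1
        for _ in range(200):
            a, b, c, d = rng.integers(1, 15, size=4)
            x = np.r_[np.ones(a + b), np.zeros(c + d)]
            y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
            fit = logistic_fit(pd.DataFrame({"e": x}), y)
            assert fit.odds_ratio("e") == pytest.approx(
                a * d / (b * c), rel=1e-5)

    def test_wald_type_one_error_under_null(self, rng):
        rejections = 0
        n_sim = 100
        for _ in range(n_sim):
            x = rng.standard_normal(2000)
            y = rng.integers(0, 2, 2000)
            fit = logistic_fit(pd.DataFrame({"x": x}), y)
            rejections += fit.table.loc["x", "p"] < 0.05
        assert abs(rejections / n_sim - 0.05) < 0.05

    def test_constant_outcome_flagged(self):
        fit = logistic_fit(pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0, 0.5]}),
                           np.ones(5))
        assert not fit.converged
        assert np.isnan(fit.table["B"]).all()

    def test_perfect_separation_names_predictor(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(PerfectSeparationError, match="sep_flag"):
            logistic_fit(pd.DataFrame({"sep_flag": x}), y)

    def test_model_chi2_and_nagelkerke(self):
        t = DYSMATURE_TABLE
        x = np.r_[np.ones(t.a + t.b), np.zeros(t.c + t.d)]
        y = np.r_[np.ones(t.a), np.zeros(t.b), np.ones(t.c), np.zeros(t.d)]
        fit = logistic_fit(pd.DataFrame({"e": x}), y)
        assert fit.model_df == 1
        assert fit.model_chi2 > 0
        assert 0 < fit.nagelkerke_r2 < 1
        assert fit.model_p < 0.05  # designed association is detectable


class TestMannWhitney:
    def test_identical_samples(self, rng):
        x = rng.standard_normal(20)
        res = mann_whitney_u(x, x.copy())
        assert res.u == pytest.approx(20 * 20 / 2)
        assert res.p > 0.9

    def test_exact_matches_enumeration_oracle(self, rng):
        # brute force over all C(8,4)=70 rank assignments
        x = np.array([1.3, 2.1, 5.2, 0.4])
        y = np.array([3.3, 7.8, 6.1, 4.9])
        res = mann_whitney_u(x, y)
        assert res.method == "exact"
        pooled = np.concatenate([x, y])
        ranks = pooled.argsort().argsort() + 1

        def u_of(idx):
            r = ranks[list(idx)].sum()
            return r - 4 * 5 / 2

        u_obs = u_of([0, 1, 2, 3])
        us = [u_of(c) for c in itertools.combinations(range(8), 4)]
        # two-sided: as extreme in either direction
        dev = abs(u_obs - 8.0)
        p_exact = np.mean([abs(u - 8.0) >= dev for u in us])
        assert res.p == pytest.approx(p_exact, abs=1e-12)

    def test_asymptotic_close_to_exact_moderate_n(self, rng):
        from scipy.stats import mannwhitneyu as sp_mwu
        for n1, n2 in ((6, 6), (8, 7), (5, 8)):
            x = rng.standard_normal(n1)
            y = rng.standard_normal(n2) + 0.5
            pe = sp_mwu(x, y, method="exact").pvalue
            pa = sp_mwu(x, y, method="asymptotic").pvalue
            assert abs(pe - pa) < 0.05

    def test_extreme_separation(self, rng):
        x = rng.standard_normal(30) + 5.0
        y = rng.standard_normal(30)
        assert mann_whitney_u(x, y).p < 1e-6

    def test_all_values_identical(self):
        res = mann_whitney_u(np.ones(5), np.ones(7))
        assert res.p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestDQTransforms:
    def test_known_points(self):
        assert transform_dq([1.0], "log")[0] == 0.0
        assert transform_dq([4.0], "reciprocal")[0] == 0.25

    @pytest.mark.parametrize("kind", ["log", "reciprocal"])
    def test_round_trip(self, kind, rng):
        v = rng.uniform(30, 150, 50)
        back = inverse_transform_dq(transform_dq(v, kind), kind)
        np.testing.assert_allclose(back, v, atol=1e-12)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            transform_dq([50.0, 0.0], "log")


class TestLinearModel:
    def test_exact_fit(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(50),
                          "b": rng.standard_normal(50)})
        y = 2.0 * X["a"] - 1.0 * X["b"] + 3.0
        res = linear_model(X, y)
        assert res.rsquared == pytest.approx(1.0)
        assert np.abs(res.resid).max() < 1e-10

    def test_parameter_recovery(self, rng):
        betas = []
        for _ in range(50):
            X = pd.DataFrame({"a": rng.standard_normal(1000),
                              "b": rng.standard_normal(1000)})
            y = 2.0 * X["a"] - 1.0 * X["b"] + rng.normal(0, 0.1, 1000)
            res = linear_model(X, y)
            betas.append([res.params["a"], res.params["b"]])
        mean_b = np.mean(betas, axis=0)
        assert abs(mean_b[0] - 2.0) < 0.02
        assert abs(mean_b[1] + 1.0) < 0.02

    def test_binary_predictor_equals_group_mean_difference(self, rng):
        g = rng.integers(0, 2, 200).astype(float)
        y = rng.standard_normal(200) + 1.5 * g
        res = linear_model(pd.DataFrame({"g": g}), y)
        diff = y[g == 1].mean() - y[g == 0].mean()
        assert res.params["g"] == pytest.approx(diff, abs=1e-10)

    def test_rank_deficient_names_columns(self, rng):
        a = rng.standard_normal(30)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(ValueError, match="'a'.*'b'"):
            linear_model(X, rng.standard_normal(30))


class TestCollinearity:
    def test_orthogonal_predictors_unit_vif(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame({"s": np.sin(2 * np.pi * t / n),
                          "c": np.cos(2 * np.pi * t / n)})
        res = collinearity_check(X)
        np.testing.assert_allclose(res["vif"], 1.0, atol=1e-10)
        np.testing.assert_allclose(res["tolerance"], 1.0, atol=1e-10)

    def test_duplicated_column_infinite_vif(self, rng):
        a = rng.standard_normal(40)
        res = collinearity_check(pd.DataFrame({"a": a, "b": a.copy()}))
        assert np.isinf(res.loc["a", "vif"])
        assert res.loc["a", "tolerance"] == 0.0

    def test_matches_r_squared_oracle(self, rng):
        import statsmodels.api as sm
        a = rng.standard_normal(200)
        b = a + rng.normal(0, 0.3, 200)
        c = rng.standard_normal(200)
        X = pd.DataFrame({"a": a, "b": b, "c": c})
        res = collinearity_check(X)
        r2 = sm.OLS(X["a"], sm.add_constant(X[["b", "c"]])).fit().rsquared
        assert res.loc["a", "vif"] == pytest.approx(1 / (1 - r2), rel=1e-6)


class TestOddsRatioLogisticAgreement:
    def test_property_over_random_tables(self, rng):
        # odds_ratio and the logistic MLE agree on every 2x2 with cells >= 1
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 12, size=4)
            t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            want = odds_ratio(t).odds_ratio
            x = np.r_[np.ones(a + b), np.zeros(c + d)]
            y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
            fit = logistic_fit(pd.DataFrame({"e": x}), y)
            assert fit.odds_ratio("e") == pytest.approx(want, rel=1e-4)
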