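import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import prseval as pe
from prseval.metrics import ConvergenceError

from conftest import auc_pair_counting, toy_cohort


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = pe.fit_logistic(y, pd.DataFrame({"const": np.ones(100)}))
        assert fit.params["const"] == pytest.approx(np.log(30 / 70), abs=1e-8)
        assert fit.n == 100 and fit.llf < 0

    def test_binary_covariate_recovers_table_log_odds_ratio(self):
        # 2x2 table: exposed 40 cases/10 controls, unexposed 20/30
        y = np.r_[np.ones(40), np.zeros(10), np.ones(20), np.zeros(30)]
        x = np.r_[np.ones(50), np.zeros(50)]
        fit = pe.fit_logistic(y, pd.DataFrame({"const": 1.0, "x": x}))
        log_or = np.log(40 * 30 / (10 * 20))  # cross-product ratio
        assert fit.params["x"] == pytest.approx(log_or, abs=1e-6)
        se = np.sqrt(1 / 40 + 1 / 10 + 1 / 20 + 1 / 30)
        assert fit.bse["x"] == pytest.approx(se, rel=1e-3)

    def test_recovers_generator_effect_within_two_se(self, small_scores):
        st_, _, std = small_scores
        y = st_.cohort.is_case.astype(float)
        fit = pe.fit_logistic(
            y,
            pd.DataFrame(
                {
                    "const": 1.0,
                    "prs": st_.truth.standardized_liability,
                    "sex": st_.cohort.samples["sex"].to_numpy(dtype=float),
                    "age": st_.cohort.samples["age_at_sampling"].to_numpy(),
                }
            ),
        )
        # case-control over-sampling shifts the intercept, not the slope
        assert (
            abs(fit.params["prs"] - st_.truth.prs_effect) < 2 * fit.bse["prs"]
        )

    def test_separation_raises(self):
        y = np.r_[np.zeros(20), np.ones(20)]
        x = np.r_[np.arange(20), 100 + np.arange(20)].astype(float)
        with pytest.raises(ConvergenceError):
            pe.fit_logistic(y, pd.DataFrame({"const": 1.0, "x": x}))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            pe.fit_logistic(np.ones(10), pd.DataFrame({"const": np.ones(10)}))


class TestNagelkerke:
    def test_full_equals_null_gives_zero(self):
        y = np.r_[np.ones(25), np.zeros(75)]
        fit = pe.fit_logistic(y, pd.DataFrame({"const": np.ones(100)}))
        assert pe.nagelkerke_r2(fit, fit) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        y = (rng.uniform(size=300) < 1 / (1 + np.exp(-x))).astype(float)
        full = pe.fit_logistic(y, pd.DataFrame({"const": 1.0, "x": x}))
        null = pe.fit_logistic(y, pd.DataFrame({"const": np.ones(300)}))
        l0, l1, n = null.llf, full.llf, 300
        expected = (1 - np.exp(2 * (l0 - l1) / n)) / (1 - np.exp(2 * l0 / n))
        assert pe.nagelkerke_r2(full, null) == pytest.approx(expected, rel=1e-12)

    def test_near_separation_approaches_one(self):
        y = np.r_[np.zeros(50), np.ones(50)]
        rng = np.random.default_rng(0)
        x = np.r_[rng.normal(0, 1, 50), rng.normal(6, 1, 50)]
        x[0], x[50] = 6.5, -0.5  # minimal overlap keeps the MLE finite
        full = pe.fit_logistic(y, pd.DataFrame({"const": 1.0, "x": x}))
        null = pe.fit_logistic(y, pd.DataFrame({"const": np.ones(100)}))
        assert pe.nagelkerke_r2(full, null) > 0.85

    def test_nesting_violation_rejected(self):
        y = np.r_[np.ones(25), np.zeros(75)]
        fit = pe.fit_logistic(y, pd.DataFrame({"const": np.ones(100)}))
        worse = pe.LogisticFit(
            params=fit.params, bse=fit.bse, zvalues=fit.zvalues,
            pvalues=fit.pvalues, llf=fit.llf - 5.0, n=fit.n,
        )
        with pytest.raises(ValueError, match="nested"):
            pe.nagelkerke_r2(worse, fit)

    def test_invariant_to_covariate_rescaling(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=400)
        y = (rng.uniform(size=400) < 1 / (1 + np.exp(-0.8 * x))).astype(float)
        null = pe.fit_logistic(y, pd.DataFrame({"const": np.ones(400)}))
        a = pe.fit_logistic(y, pd.DataFrame({"const": 1.0, "x": x}))
        b = pe.fit_logistic(y, pd.DataFrame({"const": 1.0, "x": 1000 * x}))
        assert pe.nagelkerke_r2(a, null) == pytest.approx(
            pe.nagelkerke_r2(b, null), rel=1e-6
        )


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self):
        scores = np.r_[np.zeros(5), np.ones(5)]
        labels = np.r_[np.zeros(5), np.ones(5)].astype(int)
        _, auc = pe.roc_and_auc(scores, labels)
        assert auc.auc == 1.0

    def test_independent_scores_give_half(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, 4000)
        _, auc = pe.roc_and_auc(scores, labels)
        assert abs(auc.auc - 0.5) < 0.03

    def test_toy_set_with_tie_matches_pair_counting(self):
        scores = np.array([0.1, 0.4, 0.4, 0.8, 0.2, 0.9])
        labels = np.array([0, 0, 1, 1, 0, 1])
        _, auc = pe.roc_and_auc(scores, labels)
        assert auc.auc == pytest.approx(auc_pair_counting(scores, labels))

    def test_matches_proc_delong_reference_values(self):
        # frozen from R pROC (roc/ci.auc, method="delong") on this data
        controls = [-1.2, -0.5, 0.0, 0.3, 0.3, 0.8, 1.1, -0.7]
        cases = [-0.2, 0.3, 0.9, 1.4, 0.5, 2.0]
        scores = np.array(controls + cases)
        labels = np.r_[np.zeros(8), np.ones(6)].astype(int)
        _, est = pe.roc_and_auc(scores, labels)
        assert est.auc == pytest.approx(0.7708333333, abs=1e-9)
        assert est.ci_low == pytest.approx(0.5120326064, abs=1e-9)
        assert est.ci_high == pytest.approx(1.0, abs=1e-9)

    def test_curve_monotone_with_correct_endpoints(self, small_scores):
        st_, _, std = small_scores
        roc, _ = pe.roc_and_auc(std.standardized, st_.cohort.is_case.astype(int))
        assert np.all(np.diff(roc.sensitivity) <= 0)
        assert np.all(np.diff(roc.specificity) >= 0)
        assert (roc.sensitivity[0], roc.specificity[0]) == (1.0, 0.0)
        assert (roc.sensitivity[-1], roc.specificity[-1]) == (0.0, 1.0)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            pe.roc_and_auc(np.arange(4.0), np.zeros(4, dtype=int))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_auc_equals_pair_counting_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 60)
        scores = rng.integers(0, 8, n).astype(float)  # heavy ties
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, max(1, int(n // 3)), replace=False)] = 1
        if labels.min() == labels.max():
            return
        _, auc = pe.roc_and_auc(scores, labels)
        assert auc.auc == pytest.approx(auc_pair_counting(scores, labels))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        if labels.min() == labels.max():
            return
        _, a = pe.roc_and_auc(scores, labels)
        _, b = pe.roc_and_auc(np.exp(3 * scores), labels)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)

    def test_delong_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(6)

        def width(n):
            s = np.r_[rng.normal(0, 1, n), rng.normal(0.5, 1, n)]
            y = np.r_[np.zeros(n), np.ones(n)].astype(int)
            e = pe.auc_delong(s, y)
            return e.ci_high - e.ci_low

        w_small = np.mean([width(100) for _ in range(20)])
        w_big = np.mean([width(1600) for _ in range(20)])
        assert w_big < w_small / 2.5  # ~1/sqrt(16) = 1/4, with slack


class TestDecileOr:
    def test_hand_computed_or_and_ci(self):
        # reference decile 10 cases/100 controls, top decile 40/100
        rng = np.random.default_rng(0)
        scores = np.concatenate(
            [np.full(100, k) + rng.uniform(0, 0.5, 100) for k in range(10)]
        )
        labels = np.zeros(1000, dtype=int)
        counts = [10, 12, 14, 16, 18, 20, 25, 30, 35, 40]
        case_scores, case_labels = [], []
        for k, c in enumerate(counts):
            case_scores.append(np.full(c, k) + rng.uniform(0, 0.5, c))
        scores = np.concatenate([scores, np.concatenate(case_scores)])
        labels = np.concatenate([labels, np.ones(sum(counts), dtype=int)])
        table = pe.decile_or(scores, labels)
        row = table.table.iloc[-1]
        assert row["odds_ratio"] == pytest.approx(40 * 100 / (10 * 100))
        se = np.sqrt(1 / 40 + 1 / 100 + 1 / 10 + 1 / 100)
        assert row["ci_low"] == pytest.approx(4.0 * np.exp(-1.96 * se), rel=1e-9)
        assert row["ci_high"] == pytest.approx(4.0 * np.exp(1.96 * se), rel=1e-9)

    def test_null_scores_give_or_near_one(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=6000)
        labels = (rng.uniform(size=6000) < 0.3).astype(int)
        table = pe.decile_or(scores, labels).table
        covered = (
            (table["ci_low"] <= 1.0) & (1.0 <= table["ci_high"])
        ).sum()
        assert covered >= 8

    def test_control_deciles_balanced(self, small_scores):
        st_, _, std = small_scores
        labels = st_.cohort.is_case.astype(int)
        table = pe.decile_or(std.standardized, labels)
        n_ctrl = np.r_[table.ref_control, table.table["n_control"].to_numpy()]
        assert n_ctrl.max() - n_ctrl.min() <= 1

    def test_monotone_synthetic_effect_gives_rising_trend(self, small_scores):
        st_, _, std = small_scores
        labels = st_.cohort.is_case.astype(int)
        table = pe.decile_or(std.standardized, labels).table
        log_or = np.log(table["odds_ratio"].to_numpy())
        slope = np.polyfit(table["decile"].to_numpy(), log_or, 1)[0]
        assert slope > 0
        assert table["odds_ratio"].iloc[-1] > table["odds_ratio"].iloc[0]

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError, match="10 controls"):
            pe.decile_or(np.arange(8.0), np.r_[np.zeros(4), np.ones(4)].astype(int))


class TestAaoQuartiles:
    def test_quartile_membership_on_uniform_grid(self):
        # cases with AAO 50..80: Q1 <= 57.5, Q4 > 72.5
        aao = np.arange(50.0, 81.0)
        n = aao.size
        status = np.ones(n, dtype=int)
        # add controls so the cohort is valid
        status = np.r_[status, np.zeros(5, dtype=int)]
        aao_full = np.r_[aao, np.full(5, np.nan)]
        rng = np.random.default_rng(1)
        cohort = toy_cohort(
            status, aao=aao_full,
            pc1=rng.normal(size=n + 5), pc2=rng.normal(size=n + 5),
            pc3=rng.normal(size=n + 5),
            sex=rng.integers(0, 2, n + 5),
        )
        scores = rng.normal(size=n + 5)
        res = pe.aao_quartile_analysis(cohort, scores)
        q1, q3 = np.quantile(aao, [0.25, 0.75])
        assert res.q1_cut == pytest.approx(q1)
        assert res.q3_cut == pytest.approx(q3)
        assert res.n_early == int((aao <= q1).sum())
        assert res.n_late == int((aao > q3).sum())

    def test_negative_onset_slope_gives_discrimination(self):
        cfg = pe.SimulationConfig(
            n_cases=800, n_controls=800, n_snps=30,
            aao_prs_slope=-8.0, aao_sd=8.0, seed=17,
        )
        st_ = pe.simulate_case_control_study(cfg)
        match = pe.match_variants(st_.weights, st_.panel)
        std = pe.standardize(
            pe.compute_prs(st_.panel, st_.weights, match), st_.cohort
        )
        res = pe.aao_quartile_analysis(st_.cohort, std.standardized)
        assert res.auc.auc > 0.6  # early-onset cases carry higher scores
        assert res.fit.params["prs"] > 0  # log-OR of early onset per score SD

    def test_too_few_cases_rejected(self):
        cohort = toy_cohort([1, 1, 0, 0], aao=[50, 60, np.nan, np.nan])
        with pytest.raises(ValueError, match=">= 8"):
            pe.aao_quartile_analysis(cohort, np.zeros(4))


class TestCaseControlAnalysis:
    def test_summary_consistent_with_components(self, small_scores):
        st_, _, std = small_scores
        out = pe.case_control_analysis(st_.cohort, std.standardized)
        assert out["n"] == 850
        assert 0 < out["r2_without_prs"] < out["r2_with_prs"] < 1
        assert out["prs_p_value"] < 0.05
        _, auc = pe.roc_and_auc(
            std.standardized, st_.cohort.is_case.astype(int)
        )
        assert out["auc"].auc == pytest.approx(auc.auc)
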