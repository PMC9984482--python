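"""Rank tests, logistic odds ratios, the model suite, and ROC analysis."""

import numpy as np
import pandas as pd
import pytest

from ppvstroke.inference import (
    fit_logistic,
    mann_whitney_u,
    outcome_vector,
    roc_analysis,
    run_model_suite,
    spearman_rho,
)


def rank_midrank(v):
    v = np.asarray(v, float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j < len(v) and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
        i = j
    return ranks


class TestSpearman:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [10, 20, 30], 1.0),
            ([1, 2, 3], [30, 20, 10], -1.0),
            ([1, 2, 3, 4], [2, 1, 4, 3], 0.6),
        ],
    )
    def test_known_values(self, x, y, expected):
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_matches_rank_then_pearson(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            x = rng.integers(0, 8, n).astype(float)  # heavy ties
            y = x + rng.normal(0, 2, n)
            rho, _ = spearman_rho(x, y)
            want = np.corrcoef(rank_midrank(x), rank_midrank(y))[0, 1]
            assert rho == pytest.approx(want, abs=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r0, _ = spearman_rho(x, y)
        r1, _ = spearman_rho(np.exp(x), y)
        r2, _ = spearman_rho(x, y**3)
        assert r0 == pytest.approx(r1, abs=1e-12) == pytest.approx(r2, abs=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0

    def test_interleaved_counts_pairs(self):
        # brute force: U_a = #{(a, b): a > b} = 3 with [1,3,5] vs [2,4,6]
        u, _ = mann_whitney_u([1, 3, 5], [2, 4, 6])
        assert u == 3

    def test_identical_samples_p_near_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p > 0.9

    def test_u_equals_brute_force_count(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = rng.integers(0, 12, rng.integers(3, 15)).astype(float)
            b = rng.integers(0, 12, rng.integers(3, 15)).astype(float)
            u, _ = mann_whitney_u(a, b)
            ua = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
            assert u == pytest.approx(min(ua, len(a) * len(b) - ua))

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        # cells (20,10;10,20): OR = (20*20)/(10*10) = 4
        y = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)]
        x = np.r_[np.ones(30), np.zeros(30)]
        res = fit_logistic(y, pd.DataFrame({"x": x}), "x", scale=1.0)
        assert res.converged
        assert res.or_per_10mmHg == pytest.approx(4.0, abs=1e-6)

    def test_per_10mmHg_scaling_identity(self):
        rng = np.random.default_rng(6)
        x = rng.normal(15, 5, 400)
        y = (rng.random(400) < 1 / (1 + np.exp(-(-2.5 + 0.15 * x)))).astype(float)
        r1 = fit_logistic(y, pd.DataFrame({"x": x}), "x", scale=1.0)
        r10 = fit_logistic(y, pd.DataFrame({"x": x}), "x", scale=10.0)
        assert r10.or_per_10mmHg == pytest.approx(r1.or_per_10mmHg**10, rel=1e-6)
        assert np.exp(10 * r1.coef["x"]) == pytest.approx(r10.or_per_10mmHg, rel=1e-8)

    def test_covariate_shift_leaves_or_invariant(self):
        rng = np.random.default_rng(8)
        x = rng.normal(15, 5, 500)
        z = rng.normal(0, 1, 500)
        y = (rng.random(500) < 1 / (1 + np.exp(-(-2 + 0.12 * x + 0.5 * z)))).astype(float)
        base = fit_logistic(y, pd.DataFrame({"x": x, "z": z}), "x")
        shifted = fit_logistic(y, pd.DataFrame({"x": x, "z": z + 100}), "x")
        assert shifted.or_per_10mmHg == pytest.approx(base.or_per_10mmHg, rel=1e-6)

    def test_null_predictor_or_near_one(self):
        rng = np.random.default_rng(9)
        x = rng.normal(15, 5, 2000)
        y = (rng.random(2000) < 0.4).astype(float)
        res = fit_logistic(y, pd.DataFrame({"x": x}), "x")
        # OR per 10 mmHg under the null: 1 within ~3 MC standard errors
        assert res.ci95[0] < 1.0 < res.ci95[1] or abs(np.log(res.or_per_10mmHg)) < 0.5

    def test_wald_interval_brackets_estimate(self):
        rng = np.random.default_rng(10)
        x = rng.normal(15, 5, 300)
        y = (rng.random(300) < 1 / (1 + np.exp(-(-2.5 + 0.15 * x)))).astype(float)
        res = fit_logistic(y, pd.DataFrame({"x": x}), "x")
        assert res.ci95[0] <= res.or_per_10mmHg <= res.ci95[1]
        assert res.ci95[0] > 0

    def test_duplicated_column_is_singular(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        x = np.arange(20.0)
        with pytest.raises(ValueError, match="singular"):
            fit_logistic(y, pd.DataFrame({"a": x, "b": x}), "a")

    def test_single_class_outcome_errors(self):
        with pytest.raises(ValueError, match="one class"):
            fit_logistic(np.ones(20), pd.DataFrame({"x": np.arange(20.0)}), "x")

    def test_perfect_separation_flagged_not_raised(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        x = np.arange(20.0)
        res = fit_logistic(y, pd.DataFrame({"x": x}), "x")
        assert not res.converged and res.error is not None


class TestModelSuite:
    def test_recovers_true_or_and_covariate_sets(self, default_cohort):
        cohort, _ = default_cohort
        results = run_model_suite(cohort, "sd", "30d")
        by_id = {r.model_id: r for r in results}
        assert set(by_id) == {"M1", "M2", "M3", "M4"}
        for mid in ("M1", "M2"):  # generator's true OR per 10 mmHg of SD = 4.8
            r = by_id[mid]
            assert r.converged
            assert r.ci95[0] <= 4.8 <= r.ci95[1]
        assert set(by_id["M4"].coef) == {
            "const", "sd", "thrombolysed", "mean_pp", "age", "female",
            "myocardial_infarction",
        }

    def test_zero_variance_index_fails_all_models(self, default_cohort):
        cohort, _ = default_cohort
        cohort = cohort.copy()
        cohort["sd"] = 10.0
        results = run_model_suite(cohort, "sd", "30d")
        assert all(r.error for r in results)

    def test_degenerate_outcome_fails(self, default_cohort):
        cohort, _ = default_cohort
        cohort = cohort.copy()
        cohort["mrs_30d"] = 0
        cohort["nihss_admission"] = 3
        results = run_model_suite(cohort, "sd", "30d")
        assert all(r.error for r in results)

    def test_severity_adjusted_only_in_m3(self, default_cohort):
        cohort, _ = default_cohort
        dich = outcome_vector(cohort, "30d", "dichotomized")
        sev = outcome_vector(cohort, "30d", "severity_adjusted")
        assert not dich.equals(sev)  # the generator exercises divergent cases
        by_id = {r.model_id: r for r in run_model_suite(cohort, "sd", "30d")}
        assert by_id["M3"].n_used == sev.notna().sum()


def brute_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        r = roc_analysis([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert r.youden_index == pytest.approx(1.0)
        assert r.cutoff == 3  # smallest observed score attaining max J

    def test_anti_predictive(self):
        r = roc_analysis([1, 2, 3, 4], [1, 0, 1, 0])
        assert r.auc == pytest.approx(0.25)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2, 3], [1, 1, 1])

    def test_auc_equals_mann_whitney_probability(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            n0, n1 = int(rng.integers(3, 25)), int(rng.integers(3, 25))
            scores = rng.permutation(np.arange(n0 + n1, dtype=float))  # tie-free
            labels = np.r_[np.zeros(n0), np.ones(n1)]
            r = roc_analysis(scores, labels)
            assert r.auc == brute_auc(scores, labels)

    def test_auc_with_ties_matches_brute_force(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            scores = rng.integers(0, 6, 30).astype(float)
            labels = rng.integers(0, 2, 30).astype(float)
            if labels.min() == labels.max():
                continue
            assert roc_analysis(scores, labels).auc == pytest.approx(
                brute_auc(scores, labels)
            )

    def test_delong_interval_and_p(self, default_cohort):
        cohort, _ = default_cohort
        y = (cohort["mrs_30d"] >= 3).astype(float)
        r = roc_analysis(cohort["sd"], y)
        assert 0.5 < r.auc < 1.0
        assert r.auc_ci95[0] <= r.auc <= r.auc_ci95[1]
        assert r.p_value < 0.05  # generator builds in a real effect
        assert 0 < r.youden_index < 1
        assert r.cutoff in set(cohort["sd"])
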