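"""Agreement, ROC/DeLong, Kruskal-Wallis and logistic-combination statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from mibgndb import (agreement, auc_mann_whitney, compare_rocs, fit_combined,
                     kruskal_wallis, roc)
from mibgndb.evaluation import EvaluationError


def pair_count_auc(scores, labels):
    """Exhaustive all-pairs Mann-Whitney oracle (ties count one half)."""
    cases = [s for s, l in zip(scores, labels) if l == 1]
    controls = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for c, k in itertools.product(cases, controls):
        total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(controls))


class TestAgreement:
    def test_constant_offset(self):
        x = np.array([3.0, 5.0, 9.0, 11.0])
        res = agreement(x + 2, x)
        assert res.mean_difference == pytest.approx(2.0)
        assert res.loa_lower == pytest.approx(2.0)
        assert res.loa_upper == pytest.approx(2.0)
        assert res.pearson_r == pytest.approx(1.0)

    def test_identical_constant_inputs_have_undefined_r(self):
        res = agreement([4.0, 4.0, 4.0], [4.0, 4.0, 4.0])
        assert np.isnan(res.pearson_r)
        assert res.mean_difference == 0.0
        assert (res.loa_lower, res.loa_upper) == (0.0, 0.0)

    def test_matches_textbook_formulas(self, rng):
        x = rng.normal(10, 3, 80)
        y = x + rng.normal(1.5, 0.8, 80)
        res = agreement(x, y)
        d = x - y
        sx, sy = x - x.mean(), y - y.mean()
        r_oracle = (sx * sy).sum() / np.sqrt((sx**2).sum() * (sy**2).sum())
        assert res.pearson_r == pytest.approx(r_oracle, rel=1e-10)
        assert res.mean_difference == pytest.approx(d.mean())
        assert res.loa_lower == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
        assert res.loa_upper == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
        assert res.loa_lower <= res.mean_difference <= res.loa_upper

    def test_loa_coverage_near_95_percent(self, rng):
        """Limits of agreement bracket ~95% of normal paired differences."""
        n = 5000
        x = rng.normal(20, 4, n)
        y = x + rng.normal(2.0, 1.5, n)
        res = agreement(x, y)
        d = x - y
        cover = np.mean((d >= res.loa_lower) & (d <= res.loa_upper))
        assert 0.93 <= cover <= 0.97

    def test_too_few_pairs_rejected(self):
        with pytest.raises(EvaluationError):
            agreement([1.0, 2.0], [1.0, 2.0])


class TestROC:
    def test_perfect_separation(self):
        res = roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.cutoff == pytest.approx(10.0)

    def test_uninformative_marker_near_half(self, rng):
        scores = rng.normal(0, 1, 4000)
        labels = rng.integers(0, 2, 4000)
        assert roc(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_matches_exhaustive_pair_count_on_small_fixtures(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 21))
            scores = np.round(rng.normal(0, 1, n), 1)  # rounding forces ties
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            assert auc_mann_whitney(scores, labels) == \
                pytest.approx(pair_count_auc(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        scores = rng.normal(0, 1, 300)
        labels = (rng.random(300) < 0.4).astype(int)
        assert auc_mann_whitney(scores, labels) == \
            pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_lower_direction_flips_orientation(self, rng):
        scores = np.r_[rng.normal(2.4, 0.3, 40), rng.normal(1.8, 0.3, 40)]
        labels = np.r_[np.zeros(40, int), np.ones(40, int)]
        res = roc(scores, labels, direction="lower")
        assert res.auc > 0.8
        assert res.auc == pytest.approx(1.0 - roc(scores, labels).auc)

    def test_ci_brackets_auc(self, rng):
        scores = np.r_[rng.normal(1, 1, 50), rng.normal(0, 1, 50)]
        labels = np.r_[np.ones(50, int), np.zeros(50, int)]
        res = roc(scores, labels)
        assert res.auc_ci[0] <= res.auc <= res.auc_ci[1]
        assert 0.0 <= res.auc_ci[0] and res.auc_ci[1] <= 1.0

    def test_youden_cutoff_metrics_consistent(self, rng):
        scores = np.r_[rng.normal(1.2, 1, 60), rng.normal(0, 1, 90)]
        labels = np.r_[np.ones(60, int), np.zeros(90, int)]
        res = roc(scores, labels)
        pos = scores >= res.cutoff
        assert res.sensitivity == pytest.approx(pos[labels == 1].mean())
        assert res.specificity == pytest.approx((~pos[labels == 0]).mean())

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc([1.0, 2.0, 3.0], [1, 1, 1])


class TestCompareROCs:
    def test_identical_markers_give_p_one(self, rng):
        s = rng.normal(0, 1, 60)
        y = (rng.random(60) < 0.5).astype(int)
        diff, p = compare_rocs(s, s, y)
        assert diff == 0.0 and p == 1.0

    def test_perfect_vs_noise_marker_significant(self, rng):
        y = np.r_[np.ones(40, int), np.zeros(40, int)]
        perfect = y + rng.normal(0, 0.01, 80)
        noise = rng.normal(0, 1, 80)
        diff, p = compare_rocs(perfect, noise, y)
        assert diff > 0.3 and p < 0.05

    def test_invariant_under_joint_permutation(self, rng):
        y = (rng.random(70) < 0.5).astype(int)
        a = rng.normal(y, 1.0)
        b = rng.normal(y, 2.0)
        d1, p1 = compare_rocs(a, b, y)
        perm = rng.permutation(70)
        d2, p2 = compare_rocs(a[perm], b[perm], y[perm])
        assert d1 == pytest.approx(d2) and p1 == pytest.approx(p2)

    def test_antisymmetric_in_marker_order(self, rng):
        y = (rng.random(50) < 0.5).astype(int)
        a, b = rng.normal(y, 1.0), rng.normal(0, 1, 50)
        da, pa = compare_rocs(a, b, y)
        db, pb = compare_rocs(b, a, y)
        assert da == pytest.approx(-db) and pa == pytest.approx(pb)


class TestKruskalWallis:
    def test_all_equal_values_null(self):
        res = kruskal_wallis([5.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res.h_stat == 0.0 and res.p_value == 1.0

    def test_two_groups_consistent_with_rank_sum(self, rng):
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.8, 1, 20)
        res = kruskal_wallis(np.r_[x, y], ["a"] * 25 + ["b"] * 20)
        p_mw = stats.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic", use_continuity=False).pvalue
        assert res.p_value == pytest.approx(p_mw, rel=1e-6)

    def test_three_groups_hand_ranked_oracle(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0]
        groups = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        # no ties: H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2
        rbar = [2.0, 5.0, 8.0]
        h_oracle = 12.0 / (9 * 10) * sum(3 * (r - 5.0) ** 2 for r in rbar)
        res = kruskal_wallis(values, groups)
        assert res.h_stat == pytest.approx(h_oracle, rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(EvaluationError):
            kruskal_wallis([1.0, 2.0], ["a", "a"])


class TestCombinedModel:
    def test_null_slopes_near_zero(self, rng):
        n = 3000
        h = rng.normal(2.2, 0.4, n)
        s = rng.integers(0, 20, n).astype(float)
        y = rng.integers(0, 2, n)
        model = fit_combined(h, s, y)
        assert abs(model.beta_hmr) < 0.25
        assert abs(model.beta_score) < 0.05

    def test_coefficient_recovery(self, rng):
        # single-fit standard errors sit near half the tolerance band, so
        # recovery is checked on the replicate-averaged estimate
        n = 2000
        truth = np.array([-2.0, -2.5, 2.5])  # intercept, HMR, score
        estimates = []
        for _ in range(5):
            h = rng.normal(0.0, 1.0, n)
            s = rng.normal(0.0, 1.0, n)
            logit = truth[0] + truth[1] * h + truth[2] * s
            y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
            model = fit_combined(h, s, y)
            assert model.converged
            estimates.append(model.coefficients)
        np.testing.assert_allclose(np.mean(estimates, axis=0), truth, rtol=0.10)

    def test_nested_deviance_ordering(self, small_study):
        subs = small_study["validation"]
        h = np.array([s.hmr["late"] for s in subs])
        sc = np.array([float(s.label == "CAD") * 10 + i % 5
                       for i, s in enumerate(subs)])
        y = np.array([0 if s.label == "none" else 1 for s in subs])
        model = fit_combined(h, sc, y)
        assert model.deviance <= model.deviance_hmr_only + 1e-6
        assert model.deviance <= model.deviance_score_only + 1e-6

    def test_probabilities_usable_as_roc_marker(self, rng):
        n = 400
        h = rng.normal(2.2, 0.4, n)
        s = rng.uniform(0, 20, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(2 - 2 * h + 0.2 * s)))).astype(int)
        model = fit_combined(h, s, y)
        assert np.all((model.probabilities > 0) & (model.probabilities < 1))
        auc_comb = roc(model.probabilities, y).auc
        auc_h = roc(h, y, direction="lower").auc
        auc_s = roc(s, y).auc
        assert auc_comb >= min(auc_h, auc_s) - 1e-9

    def test_perfect_separation_flagged(self):
        h = np.r_[np.full(20, 1.5), np.full(20, 2.5)] \
            + np.linspace(0, 0.01, 40)
        s = np.linspace(0, 1, 40)
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        model = fit_combined(h, s, y)
        assert model.separation_flag

    def test_constant_predictor_rejected(self):
        with pytest.raises(EvaluationError):
            fit_combined([2.0] * 10, list(range(10)), [0, 1] * 5)


def test_kruskal_wallis_null_calibration(rng):
    """Type-I error of the three-group test stays near the nominal 5%."""
    n_sim, rejections = 600, 0
    for _ in range(n_sim):
        vals = rng.normal(0, 1, 30)
        res = kruskal_wallis(vals, ["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        rejections += res.p_value < 0.05
    assert 0.02 <= rejections / n_sim <= 0.08
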