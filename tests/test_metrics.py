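"""Evaluation statistics against independent oracles and published counts."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

from sti_response import (DataError, average_precision, baseline_association_tests,
                          clopper_pearson, confusion_metrics, delong_ci, delong_test,
                          error_rate_reduction, fisher_exact_doubled, metrics_report,
                          relative_improvement, roc_auc, subgroup_report,
                          youden_threshold)
from sti_response.metrics import absolute_difference_points, continuous_association_test


def _auc_pair_oracle(scores, labels):
    """Brute-force enumeration over every positive-negative pair."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _ap_sweep_oracle(scores, labels):
    """Exhaustive threshold sweep over descending unique scores."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    ap, prev_recall = 0.0, 0.0
    n_pos = labels.sum()
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestRocAuc:
    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(5):
            scores = np.round(rng.random(30), 2)  # rounding forces ties
            labels = rng.integers(0, 2, 30)
            if labels.sum() in (0, 30):
                labels[0] = 1 - labels[0]
            assert roc_auc(scores, labels) == pytest.approx(
                _auc_pair_oracle(scores, labels), abs=1e-12)

    def test_perfect_separation_is_one(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(DataError):
            roc_auc([0.1, 0.2], [1, 1])


class TestAveragePrecision:
    def test_matches_sweep_oracle(self, rng):
        for _ in range(5):
            scores = np.round(rng.random(30), 2)
            labels = rng.integers(0, 2, 30)
            labels[0] = 1
            assert average_precision(scores, labels) == pytest.approx(
                _ap_sweep_oracle(scores, labels), abs=1e-12)

    def test_perfect_ranking_is_one(self):
        assert average_precision([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_equal_prevalence(self):
        labels = [1, 0, 0, 1, 0, 0, 0, 0, 1, 0]
        assert average_precision([0.3] * 10, labels) == pytest.approx(0.3)

    def test_no_positives_raises(self):
        with pytest.raises(DataError):
            average_precision([0.1, 0.2], [0, 0])


class TestClopperPearson:
    def test_all_successes_small_n(self):
        # 8/8 correct: lower bound is 0.025^(1/8)
        lo, hi = clopper_pearson(8, 8)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 8), abs=1e-9)
        assert round(lo, 3) == 0.631

    def test_zero_successes_lower_is_zero(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-9)

    def test_matches_binomial_tail_inversion(self):
        # independent oracle: invert the exact binomial tail probabilities
        k, n, alpha = 5, 10, 0.05
        lower = brentq(lambda p: stats.binom.sf(k - 1, n, p) - alpha / 2, 1e-9, 1 - 1e-9)
        upper = brentq(lambda p: stats.binom.cdf(k, n, p) - alpha / 2, 1e-9, 1 - 1e-9)
        lo, hi = clopper_pearson(k, n, alpha)
        assert lo == pytest.approx(lower, abs=1e-6)
        assert hi == pytest.approx(upper, abs=1e-6)

    def test_interval_contains_point_estimate(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 60))
            k = int(rng.integers(0, n + 1))
            lo, hi = clopper_pearson(k, n)
            assert lo <= k / n <= hi

    def test_zero_trials_raises(self):
        with pytest.raises(DataError):
            clopper_pearson(0, 0)


class TestDeLong:
    def test_identical_scores_give_p_one(self, rng):
        s = rng.random(40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        res = delong_test(s, s, y)
        assert res["delta"] == 0.0
        assert res["p"] == 1.0

    def test_single_model_ci_brackets_auc(self, rng):
        s = rng.random(60)
        y = (s + rng.normal(0, 0.4, 60) > 0.5).astype(int)
        y[:2] = [0, 1]
        auc, (lo, hi) = delong_ci(s, y)
        assert lo <= auc <= hi

    def test_test_and_ci_consistency(self, rng):
        # p < 0.05 iff the 95% CI of the AUC difference excludes zero
        for _ in range(10):
            y = rng.integers(0, 2, 50)
            y[:2] = [0, 1]
            a = y + rng.normal(0, 0.8, 50)
            b = y + rng.normal(0, 2.0, 50)
            res = delong_test(a, b, y)
            excludes = res["ci"][0] > 0 or res["ci"][1] < 0
            assert (res["p"] < 0.05) == excludes

    def test_variance_close_to_bootstrap(self):
        # n=40 paired simulation: DeLong variance of the AUC difference
        # should match the bootstrap variance within 20 %
        rng = np.random.default_rng(7)
        y = np.array([1] * 15 + [0] * 25)
        a = y * 0.8 + rng.normal(0, 0.7, 40)
        b = y * 0.5 + rng.normal(0, 0.9, 40)
        res = delong_test(a, b, y)
        cov = res["ci"]
        delong_var = ((cov[1] - cov[0]) / (2 * stats.norm.ppf(0.975))) ** 2
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, 40, 40)
            if len(set(y[idx])) < 2:
                continue
            boots.append(roc_auc(a[idx], y[idx]) - roc_auc(b[idx], y[idx]))
        boot_var = np.var(boots, ddof=1)
        assert delong_var == pytest.approx(boot_var, rel=0.2)

    def test_unpaired_lengths_raise(self):
        with pytest.raises(DataError):
            delong_test([1, 2], [1, 2, 3], [0, 1])


class TestConfusionMetrics:
    def test_prospective_specificity(self):
        # 37 of 41 non-pCR identified
        y = np.array([0] * 41 + [1] * 23)
        pred = np.array([0] * 37 + [1] * 4 + [1] * 19 + [0] * 4)
        rep = confusion_metrics(pred, y)
        assert round(rep.specificity, 3) == 0.902
        assert round(rep.sensitivity, 3) == 0.826
        assert rep.tn == 37 and rep.tp == 19

    def test_all_correct_gives_ones(self):
        rep = confusion_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        for m in (rep.accuracy, rep.sensitivity, rep.specificity, rep.ppv, rep.npv):
            assert m == 1.0

    def test_counts_consistent_with_metrics(self, rng):
        y = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        rep = confusion_metrics(p, y)
        assert rep.sensitivity == pytest.approx(rep.tp / max(rep.tp + rep.fn, 1))
        assert rep.tp + rep.fp + rep.tn + rep.fn == 50
        for ci, val in ((rep.sensitivity_ci, rep.sensitivity),
                        (rep.specificity_ci, rep.specificity)):
            assert ci[0] <= val <= ci[1]

    def test_length_mismatch_raises(self):
        with pytest.raises(DataError):
            confusion_metrics([1, 0], [1, 0, 1])


class TestImprovementArithmetic:
    @pytest.mark.parametrize("ref,new,expected", [
        (0.792, 0.898, 13.4),   # longitudinal + attention vs longitudinal
        (0.544, 0.898, 65.1),   # vs pre-treatment + spatial
        (0.791, 0.898, 13.5),   # vs early-treatment + spatial
        (0.537, 0.792, 47.5),   # longitudinal vs pre-treatment alone
        (0.732, 0.792, 8.2),    # longitudinal vs early-treatment alone
        (0.732, 0.791, 8.1),    # spatial added to early-treatment
        (0.537, 0.544, 1.3),    # spatial added to pre-treatment
    ])
    def test_ratio_convention_reproduces_published_percentages(self, ref, new, expected):
        assert relative_improvement(ref, new) == expected

    def test_identity_is_zero(self):
        assert relative_improvement(0.7, 0.7) == 0.0
        assert error_rate_reduction(0.3, 0.3) == 0.0

    def test_absolute_points_labeled_distinctly(self):
        assert absolute_difference_points(0.792, 0.898) == 10.6

    def test_error_rate_reduction_raw_fractions(self):
        assert error_rate_reduction(8 / 19, 4 / 23) == 58.7

    def test_error_rate_reduction_rounded_percentages(self):
        assert error_rate_reduction(26.7, 9.8) == 63.3

    def test_nonpositive_reference_raises(self):
        with pytest.raises(DataError):
            relative_improvement(0.0, 0.5)
        with pytest.raises(DataError):
            error_rate_reduction(0.0, 0.1)


class TestContingencyTests:
    def test_fisher_doubled_matches_enumeration(self, rng):
        # oracle: enumerate the hypergeometric tails directly
        for _ in range(20):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum() == 0 or t[0].sum() == 0 or t[:, 0].sum() == 0:
                continue
            a, n = t[0, 0], t.sum()
            r, c = t[0].sum(), t[:, 0].sum()
            support = range(max(0, r + c - n), min(r, c) + 1)
            pmf = {k: stats.hypergeom.pmf(k, n, c, r) for k in support}
            lower = sum(v for k, v in pmf.items() if k <= a)
            upper = sum(v for k, v in pmf.items() if k >= a)
            expected = min(1.0, 2.0 * min(lower, upper))
            assert fisher_exact_doubled(t) == pytest.approx(expected, abs=1e-10)

    def test_no_association_capped_at_one(self):
        name, p = baseline_association_tests([[3, 3], [3, 3]])
        assert name == "fisher_doubled"
        assert p == 1.0

    def test_yates_correction_matches_textbook_formula(self):
        t = np.array([[20, 30], [40, 15]], float)
        row, col, n = t.sum(1), t.sum(0), t.sum()
        expected_counts = np.outer(row, col) / n
        chi2 = ((np.abs(t - expected_counts) - 0.5) ** 2 / expected_counts).sum()
        name, p = baseline_association_tests(t)
        assert name == "chi2_yates"
        assert p == pytest.approx(stats.chi2.sf(chi2, 1), abs=1e-10)

    def test_continuous_dispatch(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.2, 1, 40)
        name, p = continuous_association_test(a, b)
        assert name == "t" and 0 <= p <= 1
        name, _ = continuous_association_test(rng.exponential(1, 60),
                                              rng.exponential(1.5, 60))
        assert name == "mannwhitney"

    def test_empty_table_raises(self):
        with pytest.raises(DataError):
            baseline_association_tests([[0, 0], [0, 0]])


class TestSubgroupReport:
    def test_single_group_equals_overall(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = y * 0.5 + rng.random(40) * 0.5
        rep = subgroup_report(s, y, ["all"] * 40, threshold=0.5)
        overall = metrics_report(s, y, threshold=0.5)
        assert rep["all"].auc == pytest.approx(overall.auc)
        assert rep["all"].tp == overall.tp

    def test_planted_heterogeneity_ordering(self, rng):
        groups, scores, labels = [], [], []
        for name, noise in (("clean", 0.1), ("noisy", 2.0)):
            y = rng.integers(0, 2, 120)
            y[:2] = [0, 1]
            s = y + rng.normal(0, noise, 120)
            groups += [name] * 120
            scores += list(s)
            labels += list(y)
        rep = subgroup_report(scores, labels, groups, threshold=0.5)
        assert rep["clean"].auc > rep["noisy"].auc

    def test_group_without_positives_is_flagged(self):
        s = [0.1, 0.4, 0.6, 0.9]
        y = [0, 0, 1, 1]
        g = ["a", "a", "b", "b"]
        rep = subgroup_report(s, y, g, threshold=0.5)
        assert rep["a"].auc is None
        assert any("single class" in f for f in rep["a"].flags)
        assert rep["a"].specificity == 1.0  # thresholded metrics still present


def test_youden_threshold_maximizes_j(rng):
    y = rng.integers(0, 2, 60)
    y[:2] = [0, 1]
    s = y * 0.6 + rng.random(60) * 0.6
    t = youden_threshold(s, y)
    pred = (s >= t).astype(int)
    rep = confusion_metrics(pred, y)
    best = rep.sensitivity + rep.specificity
    for cand in np.unique(s):
        r = confusion_metrics((s >= cand).astype(int), y)
        assert r.sensitivity + r.specificity <= best + 1e-12
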