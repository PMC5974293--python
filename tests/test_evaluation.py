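import itertools
import math

import numpy as np
import pytest

from phosctx.evaluation import (
    FPR_LEVELS,
    ConfusionCounts,
    SvmConfig,
    cross_validate,
    default_grid,
    evaluate_scores,
    mcc,
    roc_auc,
    sensitivity,
    specificity,
    threshold_at_fpr,
    train_svm,
)


def pair_count_auc(scores, labels):
    """Exhaustive positive-negative pair counting (ties count half)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0)
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_sensitivity_specificity_examples(self):
        assert sensitivity(ConfusionCounts(8, 0, 0, 2)) == pytest.approx(0.8)
        assert specificity(ConfusionCounts(0, 90, 10, 0)) == pytest.approx(0.9)
        assert sensitivity(ConfusionCounts(5, 0, 0, 0)) == 1.0

    def test_zero_denominator_flags_nan(self):
        assert math.isnan(sensitivity(ConfusionCounts(0, 10, 5, 0)))
        assert math.isnan(specificity(ConfusionCounts(3, 0, 0, 2)))

    def test_mcc_perfect_and_inverted(self):
        assert mcc(ConfusionCounts(50, 50, 0, 0)) == 1.0
        assert mcc(ConfusionCounts(0, 0, 50, 50)) == -1.0

    def test_mcc_direct_evaluation_oracle(self):
        # TP=50, TN=40, FP=10, FN=0 -> 2000 / sqrt(60*50*50*40)
        got = mcc(ConfusionCounts(50, 40, 10, 0))
        assert got == pytest.approx(2000 / math.sqrt(60 * 50 * 50 * 40), abs=1e-12)
        assert got == pytest.approx(0.8165, abs=1e-4)

    def test_mcc_zero_marginal_is_zero(self):
        assert mcc(ConfusionCounts(0, 10, 0, 5)) == 0.0

    def test_mcc_bounded_on_random_tables(self, rng):
        for _ in range(200):
            c = ConfusionCounts(*rng.integers(0, 100, size=4))
            assert -1.0 <= mcc(c) <= 1.0

    def test_counts_from_predictions(self):
        c = ConfusionCounts.from_predictions([1, 1, 0, 0], [1, 0, 1, 0])
        assert (c.TP, c.FN, c.FP, c.TN) == (1, 1, 1, 1)
        assert c.total == 4


class TestRocAuc:
    def test_perfect_ranking(self):
        auc, roc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert np.all(np.diff(roc[:, 0]) >= 0)
        assert np.all(np.diff(roc[:, 1]) >= 0)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.5, 0.6], [1, 1])

    def test_four_point_inversion_matches_pair_counting(self):
        scores = [0.9, 0.3, 0.5, 0.1]
        labels = [1, 1, 0, 0]
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)

    def test_matches_pair_counting_oracle_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 25))
            labels = np.r_[np.ones(3, int), np.zeros(n - 3, int)]
            rng.shuffle(labels)
            scores = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            if labels.sum() in (0, n):
                continue
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)

    def test_null_auc_near_half(self, rng):
        n = 1000
        labels = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        scores = rng.normal(size=n)
        auc, _ = roc_auc(scores, labels)
        n1 = n2 = n // 2
        sd = math.sqrt((n1 + n2 + 1) / (12 * n1 * n2))
        assert abs(auc - 0.5) <= 3 * sd


class TestThresholdAtFpr:
    def enumeration_oracle(self, neg, level):
        s = np.sort(np.asarray(neg, dtype=float))
        valid = [c for c in s if np.mean(s > c) <= level]
        return min(valid) if valid else float(s[-1])

    def test_100_distinct_scores_at_10pct(self, rng):
        neg = rng.permutation(np.arange(100, dtype=float))
        cut = threshold_at_fpr(neg, 0.10)
        s = np.sort(neg)[::-1]
        assert cut == s[10]  # exactly 10 negatives strictly above
        assert np.mean(neg > cut) <= 0.10

    def test_level_zero_returns_max(self, rng):
        neg = rng.normal(size=50)
        assert threshold_at_fpr(neg, 0.0) == neg.max()

    def test_tie_collapse(self):
        assert threshold_at_fpr([2.0, 2.0, 2.0], 0.3) == 2.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 60))
            neg = np.round(rng.normal(size=n), 1)  # induce ties
            level = float(rng.uniform(0, 0.5))
            assert threshold_at_fpr(neg, level) == self.enumeration_oracle(neg, level)

    def test_realized_fpr_bounded_and_tight(self, rng):
        """At the returned cutoff the realized FPR is within the level, and
        the next-lower observed candidate would violate it."""
        for _ in range(50):
            neg = rng.normal(size=80)
            level = float(rng.uniform(0.02, 0.3))
            cut = threshold_at_fpr(neg, level)
            assert np.mean(neg > cut) <= level
            lower = neg[neg < cut]
            if lower.size:
                assert np.mean(neg > lower.max()) > level


class TestSvmAndCV:
    def separable(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        X = rng.normal(size=(n, 5))
        X[:, 0] = rng.uniform(size=n) + 3.0 * y  # gap guarantees separability
        return X, y

    def test_separable_training_auc(self):
        X, y = self.separable()
        clf = train_svm(X, y, SvmConfig("linear", 1.0))
        auc, _ = roc_auc(clf.decision_function(X), y)
        assert auc == 1.0

    def test_deterministic_scores(self):
        X, y = self.separable()
        s1 = train_svm(X, y, SvmConfig("rbf", 3.0)).decision_function(X)
        s2 = train_svm(X, y, SvmConfig("rbf", 3.0)).decision_function(X)
        assert np.array_equal(s1, s2)

    def test_single_class_errors(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            train_svm(X, np.ones(4, int), SvmConfig())

    def test_cv_separable_best_auc_near_one(self):
        X, y = self.separable(n=100)
        res = cross_validate(X, y, k=5, seed=1)
        assert res.best_mean > 0.99

    def test_cv_determinism(self):
        X, y = self.separable(n=100)
        r1 = cross_validate(X, y, k=5, grid=[SvmConfig("rbf", 1.0)], seed=7)
        r2 = cross_validate(X, y, k=5, grid=[SvmConfig("rbf", 1.0)], seed=7)
        assert np.array_equal(
            r1.fold_aucs[SvmConfig("rbf", 1.0)], r2.fold_aucs[SvmConfig("rbf", 1.0)]
        )

    def test_cv_permuted_labels_near_chance(self):
        X, y = self.separable(n=120, seed=3)
        rng = np.random.default_rng(5)
        yp = rng.permutation(y)
        res = cross_validate(X, yp, k=5, grid=[SvmConfig("linear", 1.0)], seed=2)
        assert abs(res.best_mean - 0.5) <= 3 * max(res.best_sd, 0.05)

    def test_cv_tie_break_prefers_lower_C_then_linear(self):
        X, y = self.separable(n=100)
        res = cross_validate(X, y, k=5, seed=1)
        best = res.best_config
        ties = [c for c in default_grid() if res.mean_auc[c] == res.mean_auc[best]]
        expected = min(ties, key=lambda c: (c.C, 0 if c.kernel == "linear" else 1))
        assert best == expected

    def test_insufficient_class_counts(self):
        X, y = self.separable(n=10)
        with pytest.raises(ValueError):
            cross_validate(X, y, k=10)


class TestEvaluateScores:
    def test_report_contains_all_anchors(self, rng):
        n = 400
        y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        s = rng.normal(size=n) + 1.5 * y
        rep = evaluate_scores(s, y, "Y")
        assert set(rep.thresholds) == set(FPR_LEVELS["Y"])
        neg = s[y == 0]
        for level, d in rep.at_threshold.items():
            assert np.mean(neg > d["cutoff"]) <= level
            assert 0 <= d["sensitivity"] <= 1
            assert -1 <= d["mcc"] <= 1
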