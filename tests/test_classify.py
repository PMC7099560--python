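"""Ranking, forward selection, ensemble scoring and the split plan."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from msglcm.classify import (
    EnsembleParams,
    SplitPlan,
    auc_ranksum,
    evaluate_scheme,
    fit_predict,
    forward_select,
    gini_rank,
)

from oracles import trapezoid_auc

FAST = EnsembleParams(n_trees=60, max_subset_size=5)


class TestAuc:
    def test_ranksum_equals_trapezoidal(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = rng.choice(rng.random(max(3, n // 2)), size=n)  # with ties
            assert auc_ranksum(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)
            assert auc_ranksum(y, s) == pytest.approx(trapezoid_auc(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_ranksum(np.ones(5), np.random.rand(5))


class TestSplitPlan:
    def test_stratification_and_uniqueness(self):
        labels = np.r_[np.zeros(31, int), np.ones(32, int)]
        plan = SplitPlan.generate(labels, n_iterations=100, seed=5)
        seen = set()
        for train, test in plan.splits:
            assert len(train) == 31 and len(test) == 32
            assert set(train).isdisjoint(test)
            assert set(train) | set(test) == set(range(63))
            tl = labels[list(train)]
            assert (tl == 0).sum() == 15 and (tl == 1).sum() == 16
            te = labels[list(test)]
            assert (te == 0).sum() == 16 and (te == 1).sum() == 16
            seen.add(frozenset(train))
        assert len(seen) == 100

    def test_infeasible_plan_rejected(self):
        labels = np.r_[np.zeros(10, int), np.ones(10, int)]
        with pytest.raises(ValueError):
            SplitPlan.generate(labels, n_train_benign=15, n_train_malignant=16)

    def test_reproducible_by_seed(self):
        labels = np.r_[np.zeros(31, int), np.ones(32, int)]
        a = SplitPlan.generate(labels, n_iterations=10, seed=9)
        b = SplitPlan.generate(labels, n_iterations=10, seed=9)
        assert a.splits == b.splits


class TestGiniRank:
    def test_perfect_separator_ranks_first(self, rng):
        n = 40
        y = rng.integers(0, 2, n)
        x = rng.standard_normal((n, 6))
        x[:, 3] = y  # one feature equal to the label
        ranking = gini_rank(x, y, FAST, seed=0)
        assert ranking[0] == 3

    def test_identical_features_keep_index_order(self, rng):
        # identical (constant) columns give exactly tied importances, and
        # the stable tie-break preserves the original index order
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        x = np.zeros((20, 5))
        ranking = gini_rank(x, y, FAST, seed=0)
        assert list(ranking) == [0, 1, 2, 3, 4]

    def test_stronger_single_feature_ranked_above(self, rng):
        """Feature A with larger class shift outranks weaker feature B.

        Oracle: exhaustive single-threshold Gini impurity confirms A
        separates better than B."""
        n = 60
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        a = y * 3.0 + rng.standard_normal(n) * 0.3
        b = y * 0.4 + rng.standard_normal(n) * 1.0

        def best_split_gini(f):
            best = 1.0
            for t in np.unique(f):
                left, right = y[f <= t], y[f > t]
                g = 0.0
                for part in (left, right):
                    if len(part):
                        q = part.mean()
                        g += len(part) / n * 2 * q * (1 - q)
                best = min(best, g)
            return best

        assert best_split_gini(a) < best_split_gini(b)
        ranking = gini_rank(np.c_[a, b], y, FAST, seed=1)
        assert ranking[0] == 0

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            gini_rank(rng.random((10, 3)), np.zeros(10), FAST)


class TestFitPredict:
    def test_separable_data_scores_confidently(self, rng):
        n = 40
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        x = np.c_[y * 4.0, -y * 4.0] + rng.standard_normal((n, 2)) * 0.2
        test = np.array([[4.0, -4.0], [0.0, 0.0]]) + np.array([[0, 0], [0, 0]])
        scores = fit_predict(x, y, np.array([[4.0, -4.0], [-0.2, 0.1]]), FAST, seed=2)
        assert scores[0] > 0.9 and scores[1] < 0.1

    def test_ambiguous_point_scores_near_half(self, rng):
        x = np.zeros((20, 2))
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        scores = fit_predict(x, y, np.zeros((1, 2)), FAST, seed=3)
        assert 0.3 < scores[0] < 0.7

    def test_same_seed_identical_scores(self, rng):
        x = rng.standard_normal((30, 4))
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        t = rng.standard_normal((5, 4))
        a = fit_predict(x, y, t, FAST, seed=11)
        b = fit_predict(x, y, t, FAST, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_feature_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_predict(rng.random((10, 3)), np.r_[np.zeros(5), np.ones(5)],
                        rng.random((2, 4)), FAST)


class TestForwardSelect:
    def test_perfect_single_feature_selected_alone(self, rng):
        n = 40
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        x = rng.standard_normal((n, 5))
        x[:, 0] = y * 2.0  # ranking puts it first; prefix of size 1 is perfect
        subset, score = forward_select(x, y, np.arange(5), FAST, seed=0)
        assert list(subset) == [0]
        assert score > 0.95

    def test_additive_signal_grows_before_plateau(self, rng):
        """On noiseless additively-informative features, the test-scored
        prefix AUC is non-decreasing up to the signal dimension."""
        n = 60
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        x = np.zeros((n, 4))
        # each signal feature alone is weakly informative; together perfect
        parts = rng.permutation(n)
        thirds = np.array_split(parts, 3)
        for k, idx in enumerate(thirds):
            x[idx, k] = np.where(y[idx] == 1, 1.0, -1.0)
        x[:, 3] = rng.standard_normal(n) * 0.01
        params = EnsembleParams(n_trees=100, max_subset_size=4, mode="test-scored")
        scores = []
        for k in range(1, 4):
            sub, s = forward_select(
                x, y, np.arange(4), EnsembleParams(
                    n_trees=100, max_subset_size=k, mode="test-scored"),
                seed=4, test_x=x, test_y=y,
            )
            scores.append(s)
        assert scores[0] <= scores[1] <= scores[2] + 1e-9

    def test_empty_ranking_rejected(self, rng):
        with pytest.raises(ValueError):
            forward_select(rng.random((10, 2)), np.r_[np.zeros(5), np.ones(5)],
                           np.array([], dtype=int), FAST)


class TestEvaluateScheme:
    def _cohort(self, rng, n0=12, n1=12, p=8, signal=0.0):
        y = np.r_[np.zeros(n0, int), np.ones(n1, int)]
        x = rng.standard_normal((n0 + n1, p))
        x[:, 0] += y * signal
        return x, y

    def test_perfect_features_give_auc_one(self, rng):
        x, y = self._cohort(rng, signal=50.0)
        plan = SplitPlan.generate(y, n_iterations=5, n_train_benign=6,
                                  n_train_malignant=6, seed=1)
        res = evaluate_scheme(x, y, plan, FAST)
        assert res.mean_auc == 1.0
        assert (res.accuracy == 1.0).all()
        assert res.sd_auc == 0.0

    def test_null_features_near_half(self, rng):
        x, y = self._cohort(rng, n0=16, n1=16, signal=0.0)
        plan = SplitPlan.generate(y, n_iterations=12, n_train_benign=8,
                                  n_train_malignant=8, seed=2)
        res = evaluate_scheme(x, y, plan, FAST)
        se = res.sd_auc / np.sqrt(len(res.auc))
        assert abs(res.mean_auc - 0.5) <= max(3 * se, 0.15)

    def test_accuracy_is_prevalence_weighted_sens_spec(self, rng):
        x, y = self._cohort(rng, signal=1.0)
        plan = SplitPlan.generate(y, n_iterations=4, n_train_benign=6,
                                  n_train_malignant=6, seed=3)
        res = evaluate_scheme(x, y, plan, FAST)
        for k, (train, test) in enumerate(plan.splits):
            yt = y[list(test)]
            prev = yt.mean()
            combo = prev * res.sensitivity[k] + (1 - prev) * res.specificity[k]
            assert res.accuracy[k] == pytest.approx(combo, abs=1e-12)

    def test_selected_features_recorded(self, rng):
        x, y = self._cohort(rng, signal=3.0)
        plan = SplitPlan.generate(y, n_iterations=3, n_train_benign=6,
                                  n_train_malignant=6, seed=4)
        res = evaluate_scheme(x, y, plan, FAST)
        assert len(res.selected_features) == 3
        assert all(len(s) >= 1 for s in res.selected_features)
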