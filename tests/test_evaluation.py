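"""Splits, metrics and TOST equivalence testing."""

import numpy as np
import pytest
from scipy import stats

from spectropath import (
    DegenerateSampleError,
    SingleClassError,
    TooFewGroupsError,
    aggregate_cv,
    auc_binary,
    balanced_accuracy,
    loso_splits,
    make_group_kfold,
    mauc,
    regression_metrics,
    tost,
)
from spectropath.evaluation import fold_classification_report
from _oracles import brute_force_auc


class TestGroupKFold:
    def test_ten_groups_two_per_fold_no_leakage(self):
        rng = np.random.default_rng(0)
        groups = np.repeat(np.arange(10), 6)
        labels = rng.integers(0, 2, size=60)
        plan = make_group_kfold(labels, groups, k=5, seed=0)
        for train, test in plan.folds:
            assert len(set(groups[test])) == 2
            assert not set(groups[train]) & set(groups[test])

    def test_test_folds_partition_rows(self):
        rng = np.random.default_rng(1)
        groups = rng.integers(0, 7, size=40)
        labels = rng.integers(0, 2, size=40)
        plan = make_group_kfold(labels, groups, k=3, seed=1)
        all_test = np.concatenate([test for _, test in plan.folds])
        assert sorted(all_test) == list(range(40))

    def test_too_few_groups(self):
        with pytest.raises(TooFewGroupsError):
            make_group_kfold(np.zeros(6), np.repeat([0, 1], 3), k=5)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        groups = rng.integers(0, 8, size=50)
        labels = rng.integers(0, 2, size=50)
        p1 = make_group_kfold(labels, groups, k=4, seed=7)
        p2 = make_group_kfold(labels, groups, k=4, seed=7)
        for (a, b), (c, d) in zip(p1.folds, p2.folds):
            assert np.array_equal(a, c) and np.array_equal(b, d)


class TestLOSO:
    def test_one_fold_per_slide_partition(self):
        groups = np.repeat(["s1", "s2", "s3", "s4"], 5)
        plan = loso_splits(groups)
        assert plan.k == 4
        all_test = np.concatenate([t for _, t in plan.folds])
        assert sorted(all_test) == list(range(20))
        for train, test in plan.folds:
            assert len(set(groups[test])) == 1

    def test_equals_group_kfold_at_k_equal_groups(self):
        rng = np.random.default_rng(3)
        groups = np.repeat(np.arange(5), 4)
        labels = rng.integers(0, 2, size=20)
        loso = {frozenset(test) for _, test in loso_splits(groups).folds}
        kf = {frozenset(test) for _, test in make_group_kfold(labels, groups, k=5, seed=0).folds}
        assert loso == kf

    def test_single_group_raises(self):
        with pytest.raises(TooFewGroupsError):
            loso_splits(np.zeros(5))


class TestClassificationMetrics:
    def test_balanced_accuracy_cases(self):
        assert balanced_accuracy([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0
        y = np.array([0] * 9 + [1])
        assert balanced_accuracy(y, np.zeros(10, dtype=int)) == 0.5
        # confusion [[3,1],[1,3]]
        y_true = [0, 0, 0, 0, 1, 1, 1, 1]
        y_pred = [0, 0, 0, 1, 1, 1, 1, 0]
        assert balanced_accuracy(y_true, y_pred) == 0.75

    def test_auc_examples(self):
        assert auc_binary([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert auc_binary([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5
        assert auc_binary([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == 0.75

    def test_auc_single_class(self):
        with pytest.raises(SingleClassError):
            auc_binary([1, 1, 1], [0.1, 0.2, 0.3])

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_matches_exhaustive_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        s = rng.choice([0.1, 0.25, 0.5, 0.8], size=n)  # ties likely
        assert auc_binary(y, s) == pytest.approx(brute_force_auc(y, s), abs=1e-12)

    def test_mauc_macro_average(self):
        y = np.array([0, 0, 1, 1, 2, 2])
        S = np.eye(3)[y] * 0.9 + 0.05
        assert mauc(y, S) == 1.0

    def test_single_class_fold_reports_missing_auc(self):
        proba = np.array([[0.7, 0.3], [0.6, 0.4]])
        with pytest.warns(UserWarning):
            report = fold_classification_report(np.array([0, 0]), proba, np.array([0, 1]))
        assert report["auc"] is None


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m["pcc"] == 1.0 and m["mae"] == 0.0 and m["rmse"] == 0.0 and m["r2"] == 1.0

    def test_mean_prediction_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        m = regression_metrics(y, np.full(3, y.mean()))
        assert m["r2"] == pytest.approx(0.0)
        assert m["pcc"] is None  # constant prediction has no correlation

    def test_hand_computed_example(self):
        m = regression_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert m["mae"] == pytest.approx(2 / 3)
        assert m["mse"] == pytest.approx(2 / 3)
        assert m["r2"] == pytest.approx(0.0)
        assert m["rmse"] == pytest.approx(np.sqrt(m["mse"]), abs=1e-12)


class TestTOST:
    def test_tight_deltas_are_equivalent(self):
        r = tost([0.001, -0.001, 0.0005, -0.0005, 0.0])
        assert r.p_left < 0.05 and r.p_right < 0.05 and r.equivalent

    def test_large_negative_gap_not_equivalent(self):
        d = np.array([-0.20, -0.25, -0.23])
        r = tost(d)
        assert r.p_left > 0.99
        se = d.std(ddof=1) / np.sqrt(3)
        # exact t oracle (df=2 tails are heavy, so p_right ~ 1.6e-3 here)
        assert r.p_right == pytest.approx(stats.t.cdf((d.mean() - 0.03) / se, 2), abs=1e-12)
        assert r.p_right < 0.01
        assert not r.equivalent

    def test_infinite_margin_always_equivalent(self):
        r = tost([0.3, 0.1, 0.5], margin=1e6)
        assert r.equivalent and r.p_left < 1e-6 and r.p_right < 1e-6

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_t_distribution_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(rng.uniform(-0.1, 0.1), rng.uniform(0.01, 0.2), size=int(rng.integers(3, 12)))
        r = tost(d, margin=0.03, alpha=0.05)
        n, mean, sd = len(d), d.mean(), d.std(ddof=1)
        se = sd / np.sqrt(n)
        assert r.p_left == pytest.approx(1 - stats.t.cdf((mean + 0.03) / se, n - 1), abs=1e-12)
        assert r.p_right == pytest.approx(stats.t.cdf((mean - 0.03) / se, n - 1), abs=1e-12)
        # equivalence flag agrees with the CI criterion
        inside = -0.03 < r.ci90[0] and r.ci90[1] < 0.03
        assert r.equivalent == inside

    def test_degenerate_samples_raise(self):
        with pytest.raises(DegenerateSampleError):
            tost([0.1])
        with pytest.raises(DegenerateSampleError):
            tost([0.1, 0.1, 0.1])


class TestAggregateCV:
    def test_identical_folds_zero_sd(self):
        out = aggregate_cv([{"auc": 0.8}, {"auc": 0.8}])
        assert out["auc"]["mean"] == 0.8 and out["auc"]["sd"] == 0.0

    def test_two_fold_hand_computation(self):
        out = aggregate_cv([{"auc": 0.8}, {"auc": 0.9}])
        assert out["auc"]["mean"] == pytest.approx(0.85)
        assert out["auc"]["sd"] == pytest.approx(0.0707, abs=1e-4)

    def test_missing_fold_count_propagates(self):
        out = aggregate_cv([{"auc": 0.8}, {"auc": None}, {"auc": 0.9}])
        assert out["auc"]["n"] == 2 and out["auc"]["n_missing"] == 1
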