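"""Cross-validation harness: stratification, AUC ranking, SVM geometry,
confusion metrics, aggregation, model-size selection and stability."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidcv.association import mann_whitney_u
from lipidcv.crossval import (
    CVConfig,
    _smallest_argmax,
    aggregate_trials,
    auc_rank,
    confusion_metrics,
    inclusion_table,
    rank_features,
    run_repeated_cv,
    run_single_trial,
    select_model_size,
    stratified_folds,
    svm_objective,
    train_linear_svm,
)


class TestStratifiedFolds:
    def test_case_control_design_fold_counts(self, rng):
        labels = np.r_[np.ones(23, int), np.zeros(45, int)]
        assign = stratified_folds(labels, 3, rng)
        for fold in range(3):
            cases = int(((assign == fold) & (labels == 1)).sum())
            controls = int(((assign == fold) & (labels == 0)).sum())
            assert cases in (7, 8)
            assert controls == 15

    def test_balanced_small_design(self, rng):
        labels = np.r_[np.ones(6, int), np.zeros(6, int)]
        assign = stratified_folds(labels, 3, rng)
        for fold in range(3):
            assert ((assign == fold) & (labels == 1)).sum() == 2
            assert ((assign == fold) & (labels == 0)).sum() == 2

    def test_partition_property(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[:4] = [0, 0, 1, 1]
        assign = stratified_folds(labels, 4, rng)
        assert set(assign) == {0, 1, 2, 3}
        assert len(assign) == 40  # every sample in exactly one fold

    def test_class_smaller_than_k_rejected(self, rng):
        labels = np.r_[np.ones(2, int), np.zeros(10, int)]
        with pytest.raises(ValueError):
            stratified_folds(labels, 3, rng)


class TestAucRank:
    def test_enumerated_pairs(self):
        scores = [0.9, 0.4, 0.5, 0.1]
        labels = [1, 1, 0, 0]
        assert auc_rank(scores, labels) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auc_rank([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_rank([1, 1, 1, 1], [1, 1, 0, 0]) == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auc_rank([1, 2], [1, 1])

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_equals_scaled_mann_whitney_u(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(2, 8, 2)
        scores = rng.integers(0, 6, n1 + n0).astype(float)  # ties likely
        labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
        u, _ = mann_whitney_u(scores[:n1], scores[n1:])
        assert auc_rank(scores, labels) == pytest.approx(u / (n1 * n0), abs=1e-12)


class TestRankFeatures:
    def test_label_identical_feature_ranks_first(self, rng):
        y = rng.integers(0, 2, 30)
        X = pd.DataFrame({"noise": rng.normal(size=30), "oracle": y.astype(float)})
        assert rank_features(X, y)[0] == "oracle"

    def test_anti_discriminating_outranks_weak(self, rng):
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        anti = np.r_[rng.normal(-2, 0.5, 20), rng.normal(2, 0.5, 20)]  # AUC ~ 0.0
        weak = np.r_[rng.normal(0.2, 1, 20), rng.normal(0, 1, 20)]  # AUC ~ 0.55
        X = pd.DataFrame({"weak": weak, "anti": anti})
        assert rank_features(X, y) == ["anti", "weak"]

    def test_sample_order_invariance(self, rng):
        y = rng.integers(0, 2, 25)
        y[:2] = [0, 1]
        X = pd.DataFrame(rng.normal(size=(25, 6)), columns=list("abcdef"))
        perm = rng.permutation(25)
        assert rank_features(X, y) == rank_features(X.iloc[perm], y[perm])

    def test_constant_feature_ranks_last(self, rng):
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        X = pd.DataFrame({"flat": np.ones(20), "signal": np.r_[rng.normal(1, 1, 10), rng.normal(0, 1, 10)]})
        assert rank_features(X, y)[-1] == "flat"


class TestLinearSvm:
    def test_two_point_max_margin_geometry(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1, 1])
        w, b = train_linear_svm(X, y, c=100.0)
        assert w[0] == pytest.approx(1.0, abs=1e-3)
        assert b == pytest.approx(0.0, abs=1e-6)

    def test_duplicating_points_preserves_decision(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=20) > 0, 1, -1)
        if len(set(y)) < 2:
            y[0] = -y[0]
        w1, b1 = train_linear_svm(X, y, c=1.0)
        # doubling every sample doubles the hinge sum; halving c restores
        # the same objective up to scale
        w2, b2 = train_linear_svm(np.vstack([X, X]), np.r_[y, y], c=0.5)
        np.testing.assert_allclose(w1, w2, atol=1e-3)
        assert b1 == pytest.approx(b2, abs=1e-3)

    def test_label_flip_negates_model(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.where(X[:, 1] > 0.2, 1, -1)
        if len(set(y)) < 2:
            y[0] = -y[0]
        w1, b1 = train_linear_svm(X, y, c=1.0)
        w2, b2 = train_linear_svm(X, -y, c=1.0)
        np.testing.assert_allclose(w1, -w2, atol=1e-4)
        assert b1 == pytest.approx(-b2, abs=1e-4)

    def test_objective_no_worse_than_trivial_model(self, rng):
        X = rng.normal(size=(40, 5))
        y = np.where(rng.random(40) > 0.4, 1, -1)
        if len(set(y)) < 2:
            y[0] = -y[0]
        c = 1.0
        w, b = train_linear_svm(X, y, c=c)
        assert svm_objective(X, y, w, b, c) <= svm_objective(X, y, np.zeros(5), 0.0, c) + 1e-6

    def test_degenerate_identical_rows_no_crash(self):
        X = np.ones((6, 2))
        y = np.array([1, 1, 1, -1, -1, -1])
        w, _b = train_linear_svm(X, y, c=1.0)
        assert np.isfinite(w).all()


class TestConfusionMetrics:
    def test_hand_arithmetic(self):
        # TP=2, FN=1, TN=3, FP=0
        d = np.array([1.0, 1.0, -1.0, -1.0, -1.0, -1.0])
        y = np.array([1, 1, 1, 0, 0, 0])
        m = confusion_metrics(d, y)
        assert m["sensitivity"] == pytest.approx(66.67, abs=0.01)
        assert m["specificity"] == 100.0
        assert m["ppv"] == 100.0
        assert m["npv"] == pytest.approx(75.0)
        assert m["accuracy"] == pytest.approx(83.33, abs=0.01)

    def test_all_correct(self):
        m = confusion_metrics([1, 1, -1, -1], [1, 1, 0, 0])
        assert all(v == 100.0 for v in m.values())

    def test_no_positive_predictions_gives_missing_ppv(self):
        m = confusion_metrics([-1, -2, -3, -4], [1, 0, 1, 0])
        assert math.isnan(m["ppv"])
        assert m["specificity"] == 100.0


class TestAggregation:
    def test_constant_metric_zero_width(self):
        from lipidcv.crossval import TrialMetrics

        trials = [TrialMetrics(80, 0.8, 70, 90, 75, 85) for _ in range(5)]
        agg = aggregate_trials(trials)
        assert agg["auc"].ci95_low == agg["auc"].ci95_high == agg["auc"].mean

    def test_hand_arithmetic(self):
        from lipidcv.crossval import TrialMetrics

        trials = [TrialMetrics(0, a, 0, 0, 0, 0) for a in (0.7, 0.8, 0.9)]
        agg = aggregate_trials(trials)
        assert agg["auc"].mean == pytest.approx(0.8)
        assert agg["auc"].ci95_high - agg["auc"].mean == pytest.approx(0.1132, abs=2e-4)

    def test_missing_values_excluded_with_counts(self):
        from lipidcv.crossval import TrialMetrics

        trials = [
            TrialMetrics(80, 0.8, 70, 90, float("nan"), 85),
            TrialMetrics(82, 0.7, 71, 91, 60.0, 84),
        ]
        agg = aggregate_trials(trials)
        assert agg["ppv"].n_used == 1
        assert agg["ppv"].mean == pytest.approx(60.0)
        assert agg["auc"].ci95_low <= agg["auc"].mean <= agg["auc"].ci95_high


class TestModelSize:
    def test_smallest_argmax_tie_rule(self):
        assert _smallest_argmax([0.60, 0.70, 0.70, 0.65]) == 2
        assert _smallest_argmax([0.55]) == 1

    def test_strong_two_feature_signal_selected(self, rng):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 60
            y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
            X = pd.DataFrame(r.normal(size=(n, 8)), columns=[f"f{i}" for i in range(8)])
            X["f0"] += 1.6 * y
            X["f1"] -= 1.6 * y
            cfg = CVConfig(k_folds=3, repeats=10, max_features=5, seed=seed)
            n_star, curve = select_model_size(X, y, cfg)
            assert len(curve) == 5
            hits += n_star in (2, 3)
        assert hits >= 18


class TestRepeatedCV:
    def test_trial_count_and_determinism(self, rng):
        n = 30
        y = np.r_[np.ones(12, int), np.zeros(18, int)]
        X = pd.DataFrame(rng.normal(size=(n, 10)), columns=[f"f{i}" for i in range(10)])
        cfg = CVConfig(k_folds=3, repeats=7, seed=123)
        t1, c1 = run_repeated_cv(X, y, 4, cfg)
        t2, c2 = run_repeated_cv(X, y, 4, cfg)
        assert len(t1) == 21
        assert [tr.auc for tr in t1] == [tr.auc for tr in t2]
        assert c1 == c2

    def test_feature_count_validation(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        with pytest.raises(ValueError):
            run_repeated_cv(X, y, 0, CVConfig(repeats=1))
        with pytest.raises(ValueError):
            run_repeated_cv(X, y, 4, CVConfig(repeats=1))


class TestLeakage:
    def test_held_out_labels_do_not_influence_trial(self, rng):
        """Permuting held-out-fold labels must change neither the selected
        features nor the trained classifier."""
        n = 36
        y = np.tile([1, 0], 18)
        X = pd.DataFrame(rng.normal(size=(n, 12)), columns=[f"f{i:02d}" for i in range(12)])
        train_idx = np.arange(0, 24)
        test_idx = np.arange(24, 36)
        _m1, clf1 = run_single_trial(X, y, train_idx, test_idx, 5)
        y_perm = y.copy()
        y_perm[test_idx] = rng.permutation(y[test_idx])
        _m2, clf2 = run_single_trial(X, y_perm, train_idx, test_idx, 5)
        assert clf1.feature_ids == clf2.feature_ids
        np.testing.assert_array_equal(clf1.weights, clf2.weights)
        assert clf1.bias == clf2.bias
        np.testing.assert_array_equal(clf1.center, clf2.center)


class TestInclusionTable:
    def test_frequency_arithmetic(self):
        tab = inclusion_table({"TG_01": 1140, "CE_01": 0}, 1200)
        assert tab.loc[0, "feature_id"] == "TG_01"
        assert tab.loc[0, "inclusion_frequency_pct"] == pytest.approx(95.0)
        assert tab.loc[1, "inclusion_frequency_pct"] == 0.0
        assert tab.loc[1, "rank"] == 2

    def test_bounds_and_tie_break(self):
        tab = inclusion_table({"b": 5, "a": 5, "c": 10}, 10)
        assert list(tab["feature_id"]) == ["c", "a", "b"]
        assert ((tab["inclusion_frequency_pct"] >= 0) & (tab["inclusion_frequency_pct"] <= 100)).all()

    def test_count_exceeding_trials_rejected(self):
        with pytest.raises(ValueError):
            inclusion_table({"a": 11}, 10)
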