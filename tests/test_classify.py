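import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu

from nirhsi.classify import (
    NEVER_ASSIGN,
    DegenerateTrainingError,
    RocCurve,
    ThresholdPolicy,
    UndefinedRateError,
    assign_class,
    cross_validate,
    evaluate_library,
    roc_curve,
    score,
    score_many,
    select_threshold,
    train_forest,
)


def separable_data(n_per_class=20):
    """Each class has a unique private bit -> perfectly separable."""
    classes = ["PE", "PP", "PS", "other"]
    X, y = [], []
    for k, cls in enumerate(classes):
        v = np.zeros(4, dtype=np.uint8)
        v[k] = 1
        X.extend([v] * n_per_class)
        y.extend([cls] * n_per_class)
    return np.array(X), np.array(y)


class TestForest:
    def test_separable_training_set_gets_unanimous_votes(self):
        X, y = separable_data()
        model = train_forest(X, y, seed=0)
        for s, true in zip(score_many(model, X), y):
            assert s[true] == pytest.approx(1.0)

    def test_identical_features_vote_at_bootstrap_prior(self):
        # 3:1 class ratio on identical vectors -> votes near the prior.
        X = np.tile([1, 0, 1, 0], (80, 1))
        y = np.array(["PE"] * 60 + ["PP"] * 20)
        fractions = [
            score(train_forest(X, y, seed=seed), X[0])["PE"] for seed in range(5)
        ]
        assert np.mean(fractions) == pytest.approx(0.75, abs=0.1)

    def test_same_seed_reproduces_predictions(self):
        X, y = separable_data()
        m1 = train_forest(X, y, seed=7)
        m2 = train_forest(X, y, seed=7)
        probe = np.array([[1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 1, 0]], dtype=np.uint8)
        assert score_many(m1, probe) == score_many(m2, probe)

    def test_single_class_is_degenerate(self):
        X = np.zeros((10, 4))
        with pytest.raises(DegenerateTrainingError):
            train_forest(X, np.array(["PE"] * 10))

    def test_scores_sum_to_one(self):
        X, y = separable_data()
        model = train_forest(X, y, seed=0)
        rng = np.random.default_rng(0)
        probes = rng.integers(0, 2, size=(200, 4))
        for s in score_many(model, probes):
            assert sum(s.values()) == pytest.approx(1.0, abs=1e-9)

    def test_feature_length_mismatch_raises(self):
        X, y = separable_data()
        model = train_forest(X, y, seed=0)
        with pytest.raises(ValueError):
            score(model, np.zeros(7))


class TestAssignClass:
    policy = ThresholdPolicy({"PE": 0.785, "PP": 0.320, "PS": 0.5})

    def test_high_pe_score_above_cutoff_assigns_pe(self):
        assert assign_class({"PE": 0.9, "PP": 0.05, "PS": 0.05}, self.policy) == "PE"

    def test_no_score_above_cutoff_returns_other(self):
        policy = ThresholdPolicy({"PE": 0.785, "PP": 0.32})
        assert assign_class({"PE": 0.5, "PP": 0.3}, policy) == "other"

    def test_all_zero_scores_return_other(self):
        assert assign_class({"PE": 0.0, "PP": 0.0, "PS": 0.0}, self.policy) == "other"

    def test_tie_breaks_by_fixed_class_order(self):
        policy = ThresholdPolicy({"PE": 0.1, "PP": 0.1})
        assert assign_class({"PE": 0.45, "PP": 0.45}, policy) == "PE"

    def test_highest_qualifying_score_wins(self):
        policy = ThresholdPolicy({"PE": 0.1, "PP": 0.1, "PS": 0.1})
        assert assign_class({"PE": 0.3, "PP": 0.5, "PS": 0.2}, policy) == "PP"


class TestCrossValidation:
    def test_every_sample_scored_exactly_once(self):
        X, y = separable_data(30)
        oof = cross_validate(X, y, k=10, seed=0)
        assert len(oof) == len(y)
        assert oof[["PE", "PP", "PS", "other"]].notna().all().all()
        # stratified partition: each fold holds every class
        for _, fold in oof.groupby("fold"):
            assert set(fold["true_label"]) == {"PE", "PP", "PS", "other"}

    def test_separable_library_scores_its_true_class_highly(self):
        X, y = separable_data(30)
        oof = cross_validate(X, y, k=10, seed=0)
        for _, row in oof.iterrows():
            assert row[row["true_label"]] > 0.9

    def test_same_seed_gives_identical_folds(self):
        X, y = separable_data(12)
        a = cross_validate(X, y, k=4, seed=3)
        b = cross_validate(X, y, k=4, seed=3)
        assert a.equals(b)

    def test_small_class_shrinks_fold_count_with_warning(self):
        X, y = separable_data(20)
        X = np.vstack([X, np.tile([1, 1, 1, 1], (3, 1))])
        y = np.concatenate([y, ["rare"] * 3])
        with pytest.warns(RuntimeWarning, match="reducing folds"):
            oof = cross_validate(X, y, k=10, seed=0)
        assert oof["fold"].nunique() == 3

    def test_k_below_two_rejected(self):
        X, y = separable_data(5)
        with pytest.raises(ValueError):
            cross_validate(X, y, k=1)


class TestRocCurve:
    def test_perfect_separation_has_unit_auc(self):
        scores = np.array([0.9] * 5 + [0.1] * 5)
        labels = ["PE"] * 5 + ["other"] * 5
        roc = roc_curve(scores, labels, "PE")
        assert roc.auc == pytest.approx(1.0)

    def test_label_independent_scores_have_half_auc(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 1, 10_000)
        labels = np.where(rng.uniform(size=10_000) < 0.5, "PE", "other")
        roc = roc_curve(scores, labels, "PE")
        assert roc.auc == pytest.approx(0.5, abs=0.02)

    def test_three_point_curve_trapezoid_by_hand(self):
        # Points (FPR, TPR) = (0,0), (0.5,1), (1,1) -> area 0.75.
        roc = RocCurve(
            thresholds=np.array([1.0, 0.5, 0.0]),
            tpr=np.array([0.0, 1.0, 1.0]),
            fpr=np.array([0.0, 0.5, 1.0]),
            auc=float(np.trapezoid([0.0, 1.0, 1.0], [0.0, 0.5, 1.0])),
        )
        assert roc.auc == pytest.approx(0.75)

    def test_endpoints_are_included(self):
        roc = roc_curve(np.array([0.2, 0.7]), ["other", "PE"], "PE")
        assert (roc.tpr[0], roc.fpr[0]) == (0.0, 0.0)
        assert (roc.tpr[-1], roc.fpr[-1]) == (1.0, 1.0)

    def test_single_class_input_is_undefined(self):
        with pytest.raises(UndefinedRateError):
            roc_curve(np.array([0.5, 0.6]), ["PE", "PE"], "PE")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        scores=st.lists(st.floats(0, 1), min_size=4, max_size=60),
        flips=st.lists(st.booleans(), min_size=4, max_size=60),
    )
    def test_rates_are_monotone_along_the_sweep(self, scores, flips):
        n = min(len(scores), len(flips))
        labels = ["PE" if f else "other" for f in flips[:n]]
        if len(set(labels)) < 2:
            return
        roc = roc_curve(np.array(scores[:n]), labels, "PE")
        assert np.all(np.diff(roc.tpr) >= -1e-12)
        assert np.all(np.diff(roc.fpr) >= -1e-12)
        assert 0.0 <= roc.auc <= 1.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_auc_equals_mann_whitney_statistic(self, seed):
        rng = np.random.default_rng(seed)
        n_pos, n_neg = rng.integers(3, 100, size=2)
        # vote fractions are discrete -> ties between groups are exercised
        pos = rng.integers(0, 11, n_pos) / 10.0
        neg = rng.integers(0, 9, n_neg) / 10.0
        scores = np.concatenate([pos, neg])
        labels = ["PE"] * n_pos + ["other"] * n_neg
        roc = roc_curve(scores, labels, "PE")
        u = mannwhitneyu(pos, neg).statistic / (n_pos * n_neg)
        assert roc.auc == pytest.approx(u, abs=1e-9)


class TestThresholdSelection:
    def test_max_tpr_point_under_fpr_budget_is_chosen(self):
        roc = RocCurve(
            thresholds=np.array([1.0, 0.8, 0.6, 0.4, 0.0]),
            tpr=np.array([0.0, 0.6, 0.9, 0.95, 1.0]),
            fpr=np.array([0.0, 0.01, 0.05, 0.07, 1.0]),
            auc=0.9,
        )
        assert select_threshold(roc, 0.05) == pytest.approx(0.6)

    def test_no_feasible_point_returns_never_assign(self):
        roc = RocCurve(
            thresholds=np.array([1.0, 0.5, 0.0]),
            tpr=np.array([0.2, 0.8, 1.0]),
            fpr=np.array([0.2, 0.6, 1.0]),
            auc=0.6,
        )
        assert select_threshold(roc, 0.05) == NEVER_ASSIGN

    def test_relaxing_fpr_target_cannot_reduce_tpr(self):
        rng = np.random.default_rng(5)
        scores = np.clip(rng.normal(0.5, 0.25, 400), 0, 1)
        labels = np.where(
            rng.uniform(size=400) < 1 / (1 + np.exp(-(scores - 0.5) * 6)), "PE", "other"
        )
        roc = roc_curve(scores, labels, "PE")

        def tpr_at(target):
            t = select_threshold(roc, target)
            idx = int(np.argmin(np.abs(roc.thresholds - t)))
            return roc.tpr[idx]

        assert tpr_at(0.07) >= tpr_at(0.05)

    def test_selected_cutoff_respects_fpr_estimate(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            scores = rng.uniform(0, 1, 300)
            labels = np.where(rng.uniform(size=300) < scores, "PE", "other")
            roc = roc_curve(scores, labels, "PE")
            t = select_threshold(roc, 0.05)
            if t == NEVER_ASSIGN:
                continue
            idx = int(np.argmin(np.abs(roc.thresholds - t)))
            assert roc.fpr[idx] <= 0.05


class TestEvaluateLibrary:
    def test_noiseless_separable_library_is_perfect(self, noiseless_library):
        X, y = noiseless_library.feature_matrix()
        _, report = evaluate_library(X, y, k=10, seed=0)
        for cls, entry in report.items():
            assert entry["auc"] == pytest.approx(1.0)
            assert entry["tpr_at_threshold"] == pytest.approx(1.0)
            assert entry["fpr_at_threshold"] <= 0.05

    def test_noisy_library_meets_detection_band(self, library):
        # Sanity band: PE and PP detected at TPR >= 0.95 under FPR <= 0.05.
        X, y = library.feature_matrix()
        _, report = evaluate_library(X, y, k=10, seed=0, target_fpr=0.05)
        for cls in ("PE", "PP"):
            assert report[cls]["tpr_at_threshold"] >= 0.95
            assert report[cls]["fpr_at_threshold"] <= 0.05
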