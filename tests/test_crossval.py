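"""Cross-validation pipeline: ranking, selection, folds, classifiers."""

import numpy as np
import pytest
from scipy import stats

from conftest import ranksum_p_by_enumeration
from vocdx.crossval import (
    CVConfig,
    fit_predict_classifier,
    rank_features_wilcoxon,
    run_cv,
    select_top_k,
    stratified_folds,
)


class TestRankFeaturesWilcoxon:
    def test_identical_groups_give_p_one(self):
        X = np.array([[1.0], [1.0], [1.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        assert rank_features_wilcoxon(X, y)[0] == 1.0

    def test_complete_separation_matches_enumeration(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([10.0, 11.0, 12.0])
        X = np.concatenate([a, b])[:, None]
        y = np.array([0, 0, 0, 1, 1, 1])
        p = rank_features_wilcoxon(X, y)[0]
        assert p == pytest.approx(ranksum_p_by_enumeration(b, a))
        assert p == pytest.approx(2 / 20)

    @pytest.mark.parametrize("n1,n2", [(4, 4), (5, 3), (6, 7)])
    def test_random_small_samples_match_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(3):
            a, b = rng.normal(size=n1), rng.normal(0.8, size=n2)
            X = np.concatenate([b, a])[:, None]
            y = np.array([1] * n2 + [0] * n1)
            assert rank_features_wilcoxon(X, y)[0] == pytest.approx(
                ranksum_p_by_enumeration(b, a), rel=1e-9
            )

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(24, 1000))
        y = np.r_[np.zeros(12, int), np.ones(12, int)]
        p = rank_features_wilcoxon(X, y)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_single_class_fold_rejected(self):
        with pytest.raises(ValueError):
            rank_features_wilcoxon(np.ones((3, 2)), np.array([1, 1, 1]))


class TestSelectTopK:
    def test_lowest_p_selected(self):
        assert set(select_top_k(np.array([0.5, 0.01, 0.3]), 2)) == {1, 2}

    def test_tie_break_by_ascending_index(self):
        np.testing.assert_array_equal(select_top_k(np.array([0.2, 0.2, 0.2, 0.2]), 3), [0, 1, 2])

    def test_k_saturates_at_n_features(self):
        np.testing.assert_array_equal(sorted(select_top_k(np.array([0.3, 0.1]), 10)), [0, 1])


class TestStratifiedFolds:
    def test_partition_and_training_class_coverage(self):
        """Folds partition the samples, and with a 7-member minority class
        and 10 folds every training set still holds both classes."""
        y = np.r_[np.zeros(20, int), np.ones(7, int)]
        rng = np.random.default_rng(0)
        fold = stratified_folds(y, 10, rng)
        assert fold.size == 27 and set(fold) <= set(range(10))
        for f in range(10):
            train_y = y[fold != f]
            assert {0, 1} <= set(train_y)

    def test_balanced_classes_spread_evenly(self):
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        fold = stratified_folds(y, 10, np.random.default_rng(1))
        sizes = np.bincount(fold, minlength=10)
        assert sizes.min() == sizes.max() == 4


class TestFitPredictClassifier:
    def test_gradient_boosting_memorizes_training_point(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        y = (X[:, 0] > 0).astype(int)
        proba = fit_predict_classifier("gradient_boosting", X, y, X[y == 1][:1])
        assert proba[0] > 0.5

    def test_logistic_probabilities_monotone_in_feature(self):
        X = np.linspace(-2, 2, 20)[:, None]
        y = (X[:, 0] > 0).astype(int)
        grid = np.linspace(-2, 2, 9)[:, None]
        proba = fit_predict_classifier("logistic_regression", X, y, grid)
        assert np.all(np.diff(proba) >= 0)

    def test_constant_features_return_prior_rate(self):
        X = np.ones((10, 4))
        y = np.r_[np.ones(3, int), np.zeros(7, int)]
        proba = fit_predict_classifier("random_forest", X, y, np.ones((2, 4)))
        np.testing.assert_allclose(proba, 0.3)

    def test_linear_regression_clipped_to_unit_interval(self):
        X = np.linspace(0, 1, 10)[:, None]
        y = (X[:, 0] > 0.5).astype(int)
        proba = fit_predict_classifier("linear_regression", X, y, np.array([[-5.0], [5.0]]))
        assert proba.min() >= 0.0 and proba.max() <= 1.0

    def test_unknown_name_lists_supported(self):
        with pytest.raises(ValueError, match="logistic_regression"):
            fit_predict_classifier("svm", np.ones((4, 1)), np.array([0, 1, 0, 1]), np.ones((1, 1)))

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError):
            fit_predict_classifier(
                "logistic_regression", np.ones((3, 1)), np.array([1, 1, 1]), np.ones((1, 1))
            )


def _planted_matrix(n_per_class=20, n_features=200, n_informative=5, shift=2.5, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, n_features))
    y = np.r_[np.zeros(n_per_class, int), np.ones(n_per_class, int)]
    X[y == 1, :n_informative] += shift
    return X, y


class TestRunCV:
    def test_planted_marker_reaches_high_auc(self):
        X, y = _planted_matrix(shift=3.0, seed=1)
        res = run_cv(X, y, CVConfig(classifier="logistic_regression", n_features=20, seed=1))
        assert res.auc() >= 0.90

    def test_every_sample_scored_once_with_valid_folds(self):
        X, y = _planted_matrix(seed=2)
        res = run_cv(X, y, CVConfig(classifier="logistic_regression", n_features=10, seed=2))
        assert res.proba.shape == y.shape
        assert np.all((res.proba >= 0) & (res.proba <= 1))
        assert all(len(v) == 10 for v in res.selected_features.values())

    def test_reproducible_given_config(self):
        X, y = _planted_matrix(seed=3)
        cfg = CVConfig(classifier="linear_regression", n_features=10, seed=7)
        a, b = run_cv(X, y, cfg), run_cv(X, y, cfg)
        np.testing.assert_array_equal(a.proba, b.proba)
        np.testing.assert_array_equal(a.fold_id, b.fold_id)

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(5)
        aucs = []
        for rep in range(20):
            X, y = _planted_matrix(shift=3.0, seed=rep)
            yp = rng.permutation(y)
            if yp[: len(yp) // 2].sum() in (0, len(yp) // 2):
                continue
            res = run_cv(X, yp, CVConfig(classifier="logistic_regression", n_features=10, seed=rep))
            aucs.append(res.auc())
        assert 0.42 <= np.mean(aucs) <= 0.58

    def test_monotone_power_in_effect_size(self):
        """Median collated AUC is non-decreasing in the planted shift."""
        medians = []
        for shift in (0.0, 0.7, 1.4, 2.8):
            aucs = []
            for seed in range(20):
                X, y = _planted_matrix(n_per_class=15, shift=shift, seed=seed + 100)
                res = run_cv(
                    X, y, CVConfig(classifier="logistic_regression", n_features=10, seed=seed)
                )
                aucs.append(res.auc())
            medians.append(np.median(aucs))
        assert all(b >= a - 0.02 for a, b in zip(medians, medians[1:]))
        assert medians[-1] > medians[0] + 0.2

    def test_unknown_classifier_rejected_with_names(self):
        with pytest.raises(ValueError, match="gradient_boosting"):
            CVConfig(classifier="nope")

    def test_too_few_samples_per_class_rejected(self):
        X = np.ones((4, 3))
        y = np.array([0, 0, 0, 1])
        with pytest.raises(ValueError, match="at least 2"):
            run_cv(X, y, CVConfig(n_folds=2, classifier="linear_regression"))
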