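"""RBF-SVM training, evaluation metrics, and the GA parameter search."""

import numpy as np
import pytest
from sklearn.svm import SVC

from emgmotion import (
    GAConfig,
    SVMParams,
    confusion_and_metrics,
    cross_validate,
    delta_to_gamma,
    f1_score,
    ga_optimize,
    gamma_to_delta,
    predict_windows,
    train_svm,
)
from emgmotion.classify import decision_scores, rbf_kernel_matrix
from emgmotion.exceptions import ConfigError, DomainError, ValidationError


def blobs(seed=21, n=40, spread=0.3):
    rng = np.random.default_rng(seed)
    a = rng.normal((0, 0), spread, size=(n, 2))
    b = rng.normal((3, 3), spread, size=(n, 2))
    X = np.vstack([a, b])
    y = np.array(["a"] * n + ["b"] * n)
    return X, y


class TestKernelParams:
    @pytest.mark.parametrize("gamma", [1e-4, 0.025, 1.0, 371.0])
    def test_gamma_delta_conversion_is_involutive(self, gamma):
        assert delta_to_gamma(gamma_to_delta(gamma)) == pytest.approx(
            gamma, rel=1e-12
        )

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ConfigError):
            SVMParams(C=0.0, delta=1.0)
        with pytest.raises(ConfigError):
            gamma_to_delta(-1.0)

    def test_gram_matrix_is_a_valid_kernel(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((30, 5))
        gram = rbf_kernel_matrix(X, X, delta=1.3)
        assert np.allclose(gram, gram.T)
        assert np.allclose(np.diag(gram), 1.0)
        assert np.linalg.eigvalsh(gram).min() >= -1e-8


class TestTrainPredict:
    def test_separable_blobs_fit_perfectly(self):
        X, y = blobs()
        model = train_svm(X, y, SVMParams(C=1.0, delta=1.0))
        assert (predict_windows(model, X) == y).all()

    def test_rbf_shatters_xor_linear_cannot(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array(["a", "b", "b", "a"])
        rbf = train_svm(X, y, SVMParams(C=10.0, delta=0.3), scale=False)
        assert (predict_windows(rbf, X) == y).all()
        linear = SVC(kernel="linear", C=10.0).fit(X, y)
        assert (linear.predict(X) == y).mean() < 1.0

    def test_duplicating_training_points_leaves_predictions_unchanged(self):
        X, y = blobs(seed=2)
        grid = np.random.default_rng(3).uniform(-1, 4, size=(50, 2))
        base = train_svm(X, y, SVMParams(C=1.0, delta=1.0))
        doubled = train_svm(
            np.vstack([X, X]), np.concatenate([y, y]), SVMParams(C=1.0, delta=1.0)
        )
        assert np.array_equal(
            predict_windows(base, grid), predict_windows(doubled, grid)
        )

    def test_row_permutation_permutes_predictions(self):
        X, y = blobs(seed=4)
        model = train_svm(X, y)
        perm = np.random.default_rng(0).permutation(len(X))
        assert np.array_equal(
            predict_windows(model, X[perm]), predict_windows(model, X)[perm]
        )

    def test_feature_width_mismatch_names_expected_and_actual(self):
        X, y = blobs()
        model = train_svm(X, y)
        with pytest.raises(ValidationError, match=r"expects 2.*got 3"):
            predict_windows(model, np.zeros((4, 3)))

    def test_single_class_training_rejected(self):
        with pytest.raises(DomainError):
            train_svm(np.zeros((10, 2)), ["a"] * 10)

    def test_decision_function_matches_kernel_sum_oracle(self):
        """Predictions agree with the decision value recomputed by hand
        from the stored support vectors and dual coefficients."""
        X, y = blobs(seed=21, n=25, spread=1.2)  # overlapping: some slack
        params = SVMParams(C=1.0, delta=1.0)
        model = train_svm(X, y, params, scale=False)
        svc = model.svc
        assert len(svc.support_) <= 50
        pts = np.random.default_rng(6).uniform(-2, 5, size=(20, 2))
        kernel = rbf_kernel_matrix(svc.support_vectors_, pts, params.delta)
        decision = svc.dual_coef_[0] @ kernel + svc.intercept_[0]
        predicted = predict_windows(model, pts)
        expected = np.where(decision > 0, svc.classes_[1], svc.classes_[0])
        assert np.array_equal(predicted, expected)


class TestMetrics:
    def test_f1_from_precision_recall(self):
        assert round(f1_score(0.905, 0.858), 3) == 0.881
        assert f1_score(0.0, 0.0) == 0.0

    def test_perfect_predictions(self):
        y = ["a", "b", "c", "a", "b", "c"]
        report = confusion_and_metrics(y, y, classes=("a", "b", "c"))
        assert np.array_equal(report.confusion, 2 * np.eye(3, dtype=int))
        assert report.overall_accuracy == 1.0
        for metrics in report.per_class.values():
            assert metrics == {"precision": 1.0, "recall": 1.0, "f1": 1.0}

    def test_constant_predictor_hand_computed(self):
        y_true = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        y_pred = ["a"] * 9
        report = confusion_and_metrics(y_true, y_pred, classes=("a", "b", "c"))
        assert report.per_class["a"]["recall"] == 1.0
        assert report.per_class["a"]["precision"] == pytest.approx(1 / 3)
        assert report.per_class["b"]["recall"] == 0.0
        assert report.per_class["b"]["precision"] == 0.0  # zero-denominator rule
        assert any("denominator" in note for note in report.notes)

    def test_confusion_total_equals_sample_count(self):
        rng = np.random.default_rng(0)
        y_true = rng.choice(["a", "b"], size=50)
        y_pred = rng.choice(["a", "b"], size=50)
        report = confusion_and_metrics(y_true, y_pred, classes=("a", "b"))
        assert report.confusion.sum() == 50

    def test_stray_label_rejected(self):
        with pytest.raises(ValidationError):
            confusion_and_metrics(["a"], ["z"], classes=("a", "b"))


class TestCrossValidate:
    def test_perfectly_predictable_labels(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.1, (30, 1)), rng.normal(5, 0.1, (30, 1))])
        y = np.array(["lo"] * 30 + ["hi"] * 30)
        report = cross_validate(X, y, folds=5, repeats=3, seed=0)
        assert report.accuracy_mean == 1.0
        assert report.accuracy_sd == 0.0

    def test_shuffled_labels_score_near_chance(self):
        rng = np.random.default_rng(23)
        X = rng.standard_normal((500, 5))
        y = np.repeat([f"c{i}" for i in range(5)], 100)
        rng.shuffle(y)
        report = cross_validate(X, y, folds=5, repeats=10, seed=0)
        assert 0.1 <= report.accuracy_mean <= 0.3  # chance ~ 0.2

    def test_folds_partition_every_row(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.repeat(["a", "b"], 20)
        X = np.random.default_rng(0).standard_normal((40, 2))
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = np.zeros(40, dtype=int)
        for _, test_idx in skf.split(X, y):
            seen[test_idx] += 1
        assert (seen == 1).all()

    def test_class_smaller_than_fold_count_rejected(self):
        X = np.zeros((6, 2))
        y = ["a", "a", "a", "a", "a", "b"]
        with pytest.raises(DomainError):
            cross_validate(X, y, folds=5, repeats=1)


class TestGeneticAlgorithm:
    def test_history_is_nondecreasing_and_beats_default(self):
        X, y = blobs(seed=29, n=30, spread=1.5)
        ga = GAConfig(pop_size=6, generations=4, cv_folds=3, seed=29)
        params, history = ga_optimize(X, y, ga)
        assert all(b >= a for a, b in zip(history, history[1:]))
        assert params.C > 0 and params.delta > 0
        # Warm start + elitism: tuned fitness >= default-parameter fitness
        # evaluated on the identical folds.
        from sklearn.model_selection import StratifiedKFold

        from emgmotion.classify import _cv_fitness

        folds = list(
            StratifiedKFold(3, shuffle=True, random_state=29).split(X, y)
        )
        default_fit = _cv_fitness(X, y, SVMParams.default_for(2), folds, True)
        assert history[-1] >= default_fit

    def test_degenerate_single_chromosome_run(self):
        X, y = blobs(seed=1, n=12)
        ga = GAConfig(pop_size=1, generations=1, cv_folds=2, seed=0)
        params, history = ga_optimize(X, y, ga)
        # With one warm-start chromosome and elitism 1, the result is the
        # default parameter pair itself.
        default = SVMParams.default_for(2)
        assert params.C == pytest.approx(default.C)
        assert params.delta == pytest.approx(default.delta)
        assert len(history) == 2

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ConfigError):
            GAConfig(C_range=(1.0, 0.1))
        with pytest.raises(ConfigError):
            GAConfig(mutation_rate=1.5)


class TestDecisionScores:
    def test_binary_scores_expand_to_two_columns(self):
        X, y = blobs(seed=5, n=15)
        model = train_svm(X, y)
        scores = decision_scores(model, X)
        assert scores.shape == (30, 2)
        picked = np.array([model.classes[i] for i in scores.argmax(axis=1)])
        assert np.array_equal(picked, predict_windows(model, X))
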