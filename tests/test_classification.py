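"""Classifier configurations, the KNN oracle, and naive Bayes behaviour."""

import math

import numpy as np
import pytest

from threadmotion.classify import (
    CLASSIFIER_NAMES,
    GAUSSIAN_KERNEL_SCALE,
    ClassifierSpec,
    KernelNaiveBayes,
    KNNOrientationClassifier,
    default_specs,
    knn_reference,
    load_model,
    predict,
    predict_proba,
    save_model,
    train,
)
from threadmotion.errors import ParameterError


def _blobs(rng, n_per_class=30, separation=8.0, n_classes=3):
    X, y = [], []
    for c in range(n_classes):
        center = np.zeros(6)
        center[c % 6] = separation * (c + 1)
        X.append(rng.normal(size=(n_per_class, 6)) + center)
        y += [f"class_{c}"] * n_per_class
    return np.vstack(X), np.array(y)


class TestSpecs:
    def test_nine_configurations(self):
        specs = default_specs()
        assert len(specs) == 9
        assert {s.name for s in specs} == set(CLASSIFIER_NAMES)

    def test_gaussian_kernel_scale_is_sqrt_of_predictor_count(self):
        spec = next(s for s in default_specs() if s.name == "gaussian_svm")
        assert spec.hyperparameters["kernel_scale"] == pytest.approx(math.sqrt(6))
        assert round(GAUSSIAN_KERNEL_SCALE, 1) == 2.4

    def test_weighted_knn_weight_declared_inverse_square(self):
        spec = next(s for s in default_specs() if s.name == "weighted_knn")
        assert spec.hyperparameters["weight"] == "1/d^2"

    def test_unknown_name_rejected(self):
        with pytest.raises(ParameterError):
            ClassifierSpec("decision_tree")


class TestTrain:
    def test_separable_blobs_reach_perfect_training_accuracy(self):
        X, y = _blobs(np.random.default_rng(0))
        model = train(ClassifierSpec("linear_svm"), X, y)
        assert np.mean(predict(model, X) == y) == 1.0

    def test_gaussian_svm_records_sqrt6_scale(self):
        X, y = _blobs(np.random.default_rng(0))
        model = train(ClassifierSpec("gaussian_svm"), X, y)
        assert model.estimator.gamma == pytest.approx(1.0 / 6.0)

    def test_gaussian_nb_recovers_class_means(self):
        rng = np.random.default_rng(1)
        mu = {"a": np.linspace(-2, 2, 6), "b": np.linspace(3, -3, 6)}
        X = np.vstack([rng.normal(mu[c], 1.0, size=(1000, 6)) for c in ("a", "b")])
        y = np.repeat(["a", "b"], 1000)
        model = train(ClassifierSpec("gaussian_nb"), X, y)
        # undo the stored standardization to compare in raw units
        theta = model.estimator.theta_ * model.feature_std + model.feature_mean
        for i, c in enumerate(model.estimator.classes_):
            np.testing.assert_allclose(theta[i], mu[c], atol=0.15)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 6))
        with pytest.raises(ParameterError, match="2 classes"):
            train(ClassifierSpec("linear_svm"), X, np.repeat("front", 20))

    def test_nan_features_rejected(self):
        X, y = _blobs(np.random.default_rng(0))
        X[3, 2] = np.nan
        with pytest.raises(ParameterError, match="NaN"):
            train(ClassifierSpec("linear_svm"), X, y)

    def test_wrong_dimensionality_rejected(self):
        X, y = _blobs(np.random.default_rng(0))
        model = train(ClassifierSpec("linear_svm"), X, y)
        with pytest.raises(ParameterError):
            predict(model, X[:, :4])


class TestKNNBehaviour:
    def test_one_nn_predicts_own_label_on_training_points(self):
        X, y = _blobs(np.random.default_rng(2))
        knn = KNNOrientationClassifier(metric="cubic", k=1).fit(X, y)
        assert np.all(knn.predict(X) == y)

    def test_weighted_knn_exact_match_dominates_any_k(self):
        X, y = _blobs(np.random.default_rng(3))
        model = train(ClassifierSpec("weighted_knn"), X, y)
        assert np.all(predict(model, X) == y)

    def test_cosine_knn_prefers_collinear_training_point(self):
        # one training point collinear with the query, the rest near-orthogonal
        X = np.vstack(
            [
                np.array([1.0, 1.0, 0, 0, 0, 0]),
                np.array([-1.0, 1.0, 0, 0, 0, 0]) + 1e-3,
                np.array([0, 0, 1.0, -1.0, 0, 0]),
            ]
        )
        y = np.array(["target", "other", "other"])
        knn = KNNOrientationClassifier(metric="cosine", k=1).fit(X, y)
        query = np.array([[10.0, 10.0, 0, 0, 0, 0]])
        assert knn.predict(query)[0] == "target"
        assert knn_reference(X, y, query[0], k=1, metric="cosine") == "target"

    @pytest.mark.parametrize("metric", ["cosine", "cubic", "weighted"])
    def test_production_knn_matches_bruteforce_oracle(self, metric):
        rng = np.random.default_rng(7)
        X, y = _blobs(rng, n_per_class=17, separation=2.0)  # overlapping classes
        knn = KNNOrientationClassifier(metric=metric, k=10).fit(X, y)
        queries = rng.normal(scale=4.0, size=(200, 6))
        got = knn.predict(queries)
        want = [knn_reference(X, y, q, k=10, metric=metric) for q in queries]
        assert list(got) == want

    def test_all_neighbors_same_label_wins_for_any_k(self):
        X = np.random.default_rng(5).normal(size=(12, 6))
        y = np.repeat(["a", "b"], 6)
        X[:6] += 50.0
        knn = KNNOrientationClassifier(metric="cubic", k=5).fit(X, y)
        assert knn.predict(X[:1] + 0.1)[0] == "a"


class TestNaiveBayes:
    @pytest.mark.parametrize("name", ["gaussian_nb", "kernel_nb"])
    def test_posteriors_sum_to_one(self, name):
        X, y = _blobs(np.random.default_rng(4), separation=2.0)
        model = train(ClassifierSpec(name), X, y)
        proba = predict_proba(model, X[:25])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_kernel_nb_separates_bimodal_class(self):
        # class "a" is bimodal on feature 0: a single Gaussian fit would put
        # its mean mass exactly where class "b" sits; the KDE must not
        rng = np.random.default_rng(6)
        a = np.concatenate([rng.normal(-5, 0.3, 300), rng.normal(5, 0.3, 300)])
        b = rng.normal(0, 0.3, 300)
        X = np.zeros((900, 6))
        X[:, 0] = np.concatenate([a, b])
        X[:, 1:] = rng.normal(size=(900, 5))
        y = np.array(["a"] * 600 + ["b"] * 300)
        kde_model = KernelNaiveBayes().fit(X, y)
        queries = np.zeros((2, 6))
        queries[0, 0] = 5.0
        queries[1, 0] = 0.0
        assert list(kde_model.predict(queries)) == ["a", "b"]


class TestStandardizationInvariance:
    @pytest.mark.parametrize("name", ["linear_svm", "gaussian_svm", "cosine_knn", "weighted_knn"])
    def test_affine_feature_rescaling_cannot_change_predictions(self, name):
        rng = np.random.default_rng(8)
        X, y = _blobs(rng, separation=2.0)
        queries = rng.normal(scale=3.0, size=(40, 6))
        scale = np.array([1.0, 100.0, 0.01, 5.0, 2.0, 0.5])
        shift = np.array([0.0, -50.0, 3.0, 0.0, 1e4, -2.0])
        base = predict(train(ClassifierSpec(name), X, y), queries)
        moved = predict(
            train(ClassifierSpec(name), X * scale + shift, y), queries * scale + shift
        )
        assert list(base) == list(moved)


def test_model_round_trip(tmp_path):
    X, y = _blobs(np.random.default_rng(9))
    model = train(ClassifierSpec("linear_svm"), X, y)
    path = tmp_path / "model.joblib"
    save_model(model, path)
    back = load_model(path)
    assert back.spec == model.spec
    assert np.all(predict(back, X) == predict(model, X))
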