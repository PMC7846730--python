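"""The nine classifier configurations and a brute-force KNN reference.

The configuration list mirrors a desktop classification toolkit's default
gallery: three polynomial-kernel SVMs (degree 1, 2, 3), a Gaussian-kernel
SVM whose kernel scale is the square root of the predictor count (sqrt(6)
~ 2.4), Gaussian and kernel naive Bayes, and three 10-nearest-neighbour
variants (cosine distance, cubic Minkowski distance, and Euclidean with
1/distance^2 vote weights).  Features are standardized with statistics
fitted on the training split and stored in the model; SVMs use one-vs-one
multiclass reduction.

KNN voting follows explicit tie rules: a query lying exactly on a training
point takes that point's label in the weighted variant (the 1/d^2 weight is
infinite there), and tied votes go to the label whose nearest supporting
neighbour is closer.  Because a generic library vote breaks ties
differently, neighbour *search* is delegated to the library but the vote is
applied here; :func:`knn_reference` recomputes everything with plain numpy
as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import joblib
import numpy as np
from scipy.special import logsumexp
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .errors import ParameterError
from .features import N_FEATURES

MODEL_FORMAT_VERSION = 1

#: The nine configuration names, in reporting order.
CLASSIFIER_NAMES: tuple[str, ...] = (
    "cosine_knn",
    "cubic_knn",
    "weighted_knn",
    "linear_svm",
    "quadratic_svm",
    "cubic_svm",
    "gaussian_svm",
    "kernel_nb",
    "gaussian_nb",
)

#: Gaussian-kernel SVM scale: sqrt(number of predictors).
GAUSSIAN_KERNEL_SCALE = math.sqrt(N_FEATURES)


@dataclass(frozen=True)
class ClassifierSpec:
    """A named classifier configuration with its resolved hyperparameters."""

    name: str
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ParameterError(
                f"unknown classifier {self.name!r}; expected one of {CLASSIFIER_NAMES}"
            )


def default_specs() -> list[ClassifierSpec]:
    """The nine configurations with their default hyperparameters resolved."""
    hp: dict[str, dict[str, Any]] = {
        "cosine_knn": {"k": 10, "metric": "cosine"},
        "cubic_knn": {"k": 10, "metric": "cubic"},
        "weighted_knn": {"k": 10, "metric": "weighted", "weight": "1/d^2"},
        "linear_svm": {"C": 1.0},
        "quadratic_svm": {"C": 1.0, "degree": 2, "kernel_scale": 1.0},
        "cubic_svm": {"C": 1.0, "degree": 3, "kernel_scale": 1.0},
        "gaussian_svm": {"C": 1.0, "kernel_scale": GAUSSIAN_KERNEL_SCALE},
        "kernel_nb": {"bandwidth": "silverman"},
        "gaussian_nb": {},
    }
    return [ClassifierSpec(name, hp[name]) for name in CLASSIFIER_NAMES]


# ---------------------------------------------------------------------------
# Kernel naive Bayes (per-feature Gaussian KDE with Silverman bandwidth)
# ---------------------------------------------------------------------------


class KernelNaiveBayes:
    """Naive Bayes with a per-class, per-feature Gaussian kernel density.

    Bandwidths follow the normal-reference (Silverman) rule
    ``h = 0.9 * min(sd, IQR/1.34) * n^(-1/5)`` per class and feature, with a
    small floor so degenerate (constant) features stay usable.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KernelNaiveBayes":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self._train: list[np.ndarray] = []
        self._bw: list[np.ndarray] = []
        self._log_prior = np.empty(len(self.classes_))
        scale = max(float(np.std(X)), 1e-12)
        for i, cls in enumerate(self.classes_):
            Xc = X[y == cls]
            n = Xc.shape[0]
            sd = np.std(Xc, axis=0)
            iqr = np.subtract(*np.percentile(Xc, [75, 25], axis=0))
            spread = np.minimum(sd, iqr / 1.34)
            h = 0.9 * spread * n ** (-0.2)
            h = np.maximum(h, 1e-3 * scale)  # floor for near-constant features
            self._train.append(Xc)
            self._bw.append(h)
            self._log_prior[i] = np.log(n / X.shape[0])
        return self

    def _joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], len(self.classes_)))
        for i, (Xc, h) in enumerate(zip(self._train, self._bw)):
            # (m, n_c, p) standardized distances between queries and class points
            z = (X[:, None, :] - Xc[None, :, :]) / h
            log_kernel = -0.5 * z**2 - np.log(h * np.sqrt(2.0 * np.pi))
            # log mean over class points, summed over features (independence)
            feat_ll = logsumexp(log_kernel, axis=1) - np.log(Xc.shape[0])
            out[:, i] = self._log_prior[i] + feat_ll.sum(axis=1)
        return out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        jll -= logsumexp(jll, axis=1, keepdims=True)
        return np.exp(jll)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


# ---------------------------------------------------------------------------
# K-nearest neighbours with the package's vote/tie rules
# ---------------------------------------------------------------------------

_KNN_METRICS = ("cosine", "cubic", "weighted")


def _vote(labels: np.ndarray, dists: np.ndarray, weighted: bool):
    """Vote among neighbours ordered nearest-first.

    Weighted votes use 1/d^2; an exact match (d == 0) dominates.  Tied
    scores go to the label whose nearest supporting neighbour comes first.
    """
    if weighted:
        exact = dists <= 0.0
        if exact.any():
            return labels[int(np.argmax(exact))]
        weights = 1.0 / dists**2
    else:
        weights = np.ones_like(dists, dtype=float)
    scores: dict[Any, float] = {}
    first_seen: dict[Any, int] = {}
    for pos, (lab, w) in enumerate(zip(labels, weights)):
        scores[lab] = scores.get(lab, 0.0) + w
        first_seen.setdefault(lab, pos)
    best = max(scores.values())
    tied = [lab for lab, s in scores.items() if s == best]
    return min(tied, key=lambda lab: first_seen[lab])


class KNNOrientationClassifier:
    """KNN in one of the three configured flavours.

    metric: "cosine" (1 - cosine similarity, majority vote), "cubic"
    (Minkowski exponent 3, majority vote) or "weighted" (Euclidean,
    1/d^2 vote weights).
    """

    def __init__(self, metric: str, k: int = 10) -> None:
        if metric not in _KNN_METRICS:
            raise ParameterError(f"metric must be one of {_KNN_METRICS}, got {metric!r}")
        self.metric = metric
        self.k = k

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KNNOrientationClassifier":
        X = np.asarray(X, dtype=float)
        self._y = np.asarray(y)
        self.classes_ = np.unique(self._y)
        if self.metric == "cosine":
            nn = NearestNeighbors(metric="cosine", algorithm="brute")
        elif self.metric == "cubic":
            nn = NearestNeighbors(metric="minkowski", p=3)
        else:
            nn = NearestNeighbors(metric="euclidean")
        self._nn = nn.fit(X)
        self._n_train = X.shape[0]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        k = min(self.k, self._n_train)
        dists, idx = self._nn.kneighbors(np.asarray(X, dtype=float), n_neighbors=k)
        out = np.empty(X.shape[0], dtype=self._y.dtype)
        weighted = self.metric == "weighted"
        for i in range(X.shape[0]):
            out[i] = _vote(self._y[idx[i]], dists[i], weighted)
        return out


def knn_reference(
    train_X: np.ndarray,
    train_y: np.ndarray,
    query: np.ndarray,
    k: int = 10,
    metric: str = "cosine",
):
    """Brute-force single-query KNN oracle, independent of the library search.

    Distances, neighbour selection and voting are all recomputed with plain
    numpy under the same declared rules as the production classifier.
    """
    if metric not in _KNN_METRICS:
        raise ParameterError(f"metric must be one of {_KNN_METRICS}, got {metric!r}")
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_y)
    q = np.asarray(query, dtype=float)
    k = min(k, X.shape[0])
    diff = X - q
    if metric == "cosine":
        norms = np.linalg.norm(X, axis=1) * np.linalg.norm(q)
        norms = np.where(norms == 0.0, 1.0, norms)
        d = 1.0 - (X @ q) / norms
    elif metric == "cubic":
        d = np.sum(np.abs(diff) ** 3, axis=1) ** (1.0 / 3.0)
    else:
        d = np.sqrt(np.sum(diff**2, axis=1))
    order = np.argsort(d, kind="stable")[:k]
    nd, nl = d[order], y[order]

    if metric == "weighted":
        if nd[0] <= 0.0:
            return nl[0]
        w = 1.0 / nd**2
    else:
        w = np.ones_like(nd)
    totals: dict[Any, float] = {}
    nearest_rank: dict[Any, int] = {}
    for rank, (lab, wt) in enumerate(zip(nl, w)):
        totals[lab] = totals.get(lab, 0.0) + wt
        if lab not in nearest_rank:
            nearest_rank[lab] = rank
    top = max(totals.values())
    winners = [lab for lab, s in totals.items() if s == top]
    winners.sort(key=lambda lab: nearest_rank[lab])
    return winners[0]


# ---------------------------------------------------------------------------
# Training front-end: standardization + estimator dispatch
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """A fitted classifier plus the training-split standardization statistics."""

    spec: ClassifierSpec
    estimator: Any
    feature_mean: np.ndarray
    feature_std: np.ndarray
    classes: np.ndarray

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.feature_mean) / self.feature_std


def _build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    name = spec.name
    if name == "linear_svm":
        return SVC(kernel="linear", C=hp.get("C", 1.0))
    if name in ("quadratic_svm", "cubic_svm"):
        degree = hp.get("degree", 2 if name == "quadratic_svm" else 3)
        scale = hp.get("kernel_scale", 1.0)
        return SVC(
            kernel="poly", degree=degree, gamma=1.0 / scale**2, coef0=1.0,
            C=hp.get("C", 1.0),
        )
    if name == "gaussian_svm":
        scale = hp.get("kernel_scale", GAUSSIAN_KERNEL_SCALE)
        return SVC(kernel="rbf", gamma=1.0 / scale**2, C=hp.get("C", 1.0))
    if name == "gaussian_nb":
        return GaussianNB()
    if name == "kernel_nb":
        return KernelNaiveBayes()
    metric = {"cosine_knn": "cosine", "cubic_knn": "cubic", "weighted_knn": "weighted"}
    return KNNOrientationClassifier(metric=metric[name], k=hp.get("k", 10))


def train(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray) -> TrainedModel:
    """Fit one configuration on a training split.

    Features are standardized with the split's own mean and standard
    deviation (stored in the returned model and re-applied at prediction),
    so translating or rescaling a raw feature column cannot change what any
    distance- or margin-based configuration predicts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ParameterError(
            f"expected a (n, {N_FEATURES}) feature matrix, got shape {X.shape}"
        )
    if np.isnan(X).any():
        raise ParameterError("feature matrix contains NaN values")
    classes = np.unique(y)
    if classes.size < 2:
        raise ParameterError("training set must contain at least 2 classes")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std == 0.0, 1.0, std)
    estimator = _build_estimator(spec)
    estimator.fit((X - mean) / std, y)
    return TrainedModel(
        spec=spec, estimator=estimator, feature_mean=mean, feature_std=std,
        classes=classes,
    )


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Predict one orientation label per feature vector."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != N_FEATURES:
        raise ParameterError(
            f"expected {N_FEATURES} feature columns, got {X.shape[1]}"
        )
    return model.estimator.predict(model.standardize(X))


def predict_proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Class posteriors for models that define them (the naive Bayes pair)."""
    if not hasattr(model.estimator, "predict_proba"):
        raise ParameterError(f"{model.spec.name} does not expose posteriors")
    return model.estimator.predict_proba(model.standardize(np.asarray(X, dtype=float)))


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path: str | Path) -> TrainedModel:
    doc = joblib.load(path)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ParameterError(f"unsupported model file version: {doc.get('format_version')}")
    return doc["model"]
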