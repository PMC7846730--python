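"""Repeated random-subsampling evaluation of the nine configurations.

For each of ``reps`` rounds (default 100) one shared random split is drawn
— ``train_frac`` (default 75%) of the segments train every configuration,
the remainder test them — so all nine classifiers see identical splits and
between-classifier comparisons are paired.  Per-round accuracies are
averaged and confusion matrices pooled over rounds.

The report object carries everything a reader of the result needs: the
per-classifier averaged accuracy (the headline number), per-round
accuracies, pooled 9x9 confusion matrices in a fixed orientation order, and
the protocol, with a ``summary()`` table for quick reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix

from .classify import ClassifierSpec, default_specs, predict, train
from .errors import ParameterError
from .orientations import ORIENTATION_ORDER, Orientation, are_adjacent

logger = logging.getLogger(__name__)

#: Confusion-matrix row/column order (stable report diffs).
LABEL_ORDER: tuple[str, ...] = tuple(str(o) for o in ORIENTATION_ORDER)


@dataclass
class EvaluationReport:
    """Results container for one repeated-holdout run."""

    accuracies: dict[str, np.ndarray]  # per classifier, shape (reps,)
    confusions: dict[str, np.ndarray]  # per classifier, pooled (9, 9) counts
    reps: int
    train_frac: float
    seed: int
    n_segments: int
    label_order: tuple[str, ...] = field(default=LABEL_ORDER)

    def averaged_accuracy(self, name: str) -> float:
        """Mean of the per-repetition test accuracies (the Table-1 analogue)."""
        return float(np.mean(self.accuracies[name]))

    def pooled_accuracy(self, name: str) -> float:
        cm = self.confusions[name]
        return float(np.trace(cm) / cm.sum())

    @property
    def classifier_names(self) -> list[str]:
        return list(self.accuracies)

    def min_averaged_accuracy(self) -> float:
        return min(self.averaged_accuracy(n) for n in self.classifier_names)

    def summary(self) -> str:
        """Plain-text table of averaged testing accuracy per classifier."""
        width = max(len(n) for n in self.classifier_names)
        lines = [
            f"Repeated holdout: {self.reps} reps, "
            f"{self.train_frac:.0%} train, {self.n_segments} segments, seed {self.seed}",
            f"{'classifier':<{width}}  averaged testing accuracy",
        ]
        for name in self.classifier_names:
            lines.append(f"{name:<{width}}  {100 * self.averaged_accuracy(name):.1f}%")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "protocol": {
                "reps": self.reps,
                "train_frac": self.train_frac,
                "seed": self.seed,
                "n_segments": self.n_segments,
            },
            "orientation_order": list(self.label_order),
            "classifiers": {
                name: {
                    "averaged_accuracy": self.averaged_accuracy(name),
                    "accuracies": [float(a) for a in self.accuracies[name]],
                    "confusion": self.confusions[name].tolist(),
                }
                for name in self.classifier_names
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "EvaluationReport":
        proto = doc["protocol"]
        return cls(
            accuracies={
                name: np.asarray(entry["accuracies"], dtype=float)
                for name, entry in doc["classifiers"].items()
            },
            confusions={
                name: np.asarray(entry["confusion"], dtype=int)
                for name, entry in doc["classifiers"].items()
            },
            reps=proto["reps"],
            train_frac=proto["train_frac"],
            seed=proto["seed"],
            n_segments=proto["n_segments"],
            label_order=tuple(doc["orientation_order"]),
        )


def _draw_split(
    rng: np.random.Generator, y: np.ndarray, n_train: int, max_attempts: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Simple random split; redrawn if the training part misses a class."""
    classes = set(np.unique(y))
    for attempt in range(max_attempts):
        perm = rng.permutation(y.size)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        if set(np.unique(y[train_idx])) == classes:
            if attempt:
                logger.info("resampled split %d time(s) to cover all classes", attempt)
            return train_idx, test_idx
    raise ParameterError(
        "could not draw a training split containing every class; "
        "some class is too rare for this train fraction"
    )


def repeated_holdout(
    X: np.ndarray,
    y: np.ndarray,
    specs: list[ClassifierSpec] | None = None,
    reps: int = 100,
    train_frac: float = 0.75,
    seed: int = 0,
) -> EvaluationReport:
    """Run the full repeated random-subsampling protocol.

    With 400 segments and the default 75% train fraction, each round trains
    on 300 segments and tests on the remaining 100.  Deterministic for a
    fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    if not (0.0 < train_frac < 1.0):
        raise ParameterError("train_frac must lie in (0, 1)")
    if np.unique(y).size < 2:
        raise ParameterError("need at least 2 classes to evaluate")
    specs = specs if specs is not None else default_specs()
    n_train = int(round(train_frac * y.size))
    if not (0 < n_train < y.size):
        raise ParameterError("split leaves an empty train or test set")
    rng = np.random.default_rng(seed)
    labels = list(LABEL_ORDER)
    accuracies = {s.name: np.empty(reps) for s in specs}
    confusions = {s.name: np.zeros((len(labels), len(labels)), dtype=int) for s in specs}
    for rep in range(reps):
        train_idx, test_idx = _draw_split(rng, y, n_train)
        X_tr, y_tr = X[train_idx], y[train_idx]
        X_te, y_te = X[test_idx], y[test_idx]
        for spec in specs:
            model = train(spec, X_tr, y_tr)
            pred = predict(model, X_te)
            accuracies[spec.name][rep] = float(np.mean(pred == y_te))
            confusions[spec.name] += confusion_matrix(y_te, pred, labels=labels)
    return EvaluationReport(
        accuracies=accuracies,
        confusions=confusions,
        reps=reps,
        train_frac=train_frac,
        seed=seed,
        n_segments=int(y.size),
    )


def adjacency_error_fraction(cm: np.ndarray, label_order=LABEL_ORDER) -> float:
    """Fraction of misclassified counts whose (true, predicted) pair is
    axis-adjacent (e.g. left <-> front-left).  A diagonal matrix has no
    errors to attribute and returns 1 by convention."""
    cm = np.asarray(cm)
    if cm.shape != (len(label_order), len(label_order)):
        raise ParameterError(f"expected a {len(label_order)}x{len(label_order)} matrix")
    orients = [Orientation(lab) for lab in label_order]
    off_total = cm.sum() - np.trace(cm)
    if off_total == 0:
        logger.info("confusion matrix has no errors; adjacency fraction is 1 by convention")
        return 1.0
    adjacent = sum(
        cm[i, j]
        for i, a in enumerate(orients)
        for j, b in enumerate(orients)
        if i != j and are_adjacent(a, b)
    )
    return float(adjacent / off_total)
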