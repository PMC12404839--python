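"""Maximum-margin classification and leave-one-out evaluation.

The classifier is a soft-margin SVM (linear kernel by default, C = 1.0) over
standardized feature vectors; labels are +1 (epileptic) and -1 (normal).
Standardization parameters are fit on each training fold only.  Evaluation
uses leave-one-out cross-validation and confusion-matrix metrics expressed as
percentages: precision, recall, F score (harmonic mean), accuracy and false
positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ConfusionCounts",
    "MarginModel",
    "train",
    "predict",
    "loo_cv",
    "precision",
    "recall",
    "f_score",
    "accuracy",
    "fp_rate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN counts with positives = label +1."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == -1) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == -1))),
            tn=int(np.sum((y_true == -1) & (y_pred == -1))),
        )


@dataclass
class MarginModel:
    """A trained soft-margin classifier (scaler + SVM pipeline)."""

    pipeline: Pipeline
    kernel: str
    c: float

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        return self.pipeline.decision_function(np.atleast_2d(x))


def train(
    features: np.ndarray,
    labels: Sequence[int],
    kernel: str = "linear",
    c: float = 1.0,
) -> MarginModel:
    """Fit the margin classifier; features are z-scored inside the pipeline."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if not np.isfinite(x).all():
        raise ValueError("features must be finite")
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("both labels (-1 and +1) must be present")
    pipe = Pipeline(
        [("scale", StandardScaler()), ("svm", SVC(kernel=kernel, C=c))]
    )
    pipe.fit(x, y)
    return MarginModel(pipeline=pipe, kernel=kernel, c=c)


def predict(model: MarginModel, features: np.ndarray) -> np.ndarray:
    """Predicted labels in {-1, +1}; an exact-zero margin maps to +1."""
    d = model.decision_function(features)
    return np.where(d >= 0, 1, -1)


def loo_cv(
    features: np.ndarray,
    labels: Sequence[int],
    kernel: str = "linear",
    c: float = 1.0,
    on_degenerate: str = "abstain",
) -> ConfusionCounts:
    """Leave-one-out cross-validation.

    Each sample is tested once against a model trained on the other ``n - 1``.
    A training fold that collapses to a single class (possible only when one
    class has a single member) cannot produce a margin classifier; by default
    the held-out sample is an abstention, counted as a misclassification, so
    the confusion counts still sum to ``n``.  ``on_degenerate="raise"``
    turns this into an error instead.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = len(y)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    preds = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            if on_degenerate == "raise":
                raise ValueError(f"training fold for sample {i} is single-class")
            preds[i] = -y[i]  # abstention counted against the classifier
            continue
        model = train(x[mask], y[mask], kernel=kernel, c=c)
        preds[i] = predict(model, x[i])[0]
    return ConfusionCounts.from_labels(y, preds)


def precision(c: ConfusionCounts) -> float:
    """100 * TP / (TP + FP)."""
    if c.tp + c.fp == 0:
        raise ZeroDivisionError("no positive predictions")
    return 100.0 * c.tp / (c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    """100 * TP / (TP + FN)."""
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("no positive instances")
    return 100.0 * c.tp / (c.tp + c.fn)


def f_score(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall (percent in, percent out)."""
    if precision_pct + recall_pct == 0:
        raise ZeroDivisionError("precision and recall both zero")
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


def accuracy(c: ConfusionCounts) -> float:
    """100 * (TP + TN) / total."""
    if c.total == 0:
        raise ZeroDivisionError("empty confusion counts")
    return 100.0 * (c.tp + c.tn) / c.total


def fp_rate(c: ConfusionCounts) -> float:
    """100 * FP / (FP + TN)."""
    if c.fp + c.tn == 0:
        raise ZeroDivisionError("no negative instances")
    return 100.0 * c.fp / (c.fp + c.tn)
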