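"""Model evaluation: multiclass classification reports and calibration
(regression) statistics.

Classification uses the one-vs-rest counts TP/TN/FP/FN per class with

    accuracy  = (TP + TN) / (TP + TN + FP + FN)   on the multiclass totals
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 TP / (2 TP + FP + FN)

aggregated by class-support weighting.  Weighted recall is algebraically
identical to the overall accuracy — sum_k (n_k/N)(TP_k/n_k) = sum_k TP_k/N
— which is why published per-model recall columns systematically equal the
test-set accuracy.

Regression reports carry R^2 = 1 - SS_res/SS_tot, RMSE and the mean
relative error MRE = mean(|pred - ref| / ref), tagged with a ``cv`` or
``prediction`` context to distinguish cross-validated training statistics
(Rv2, RMSECV, MRECV) from held-out prediction statistics (Rp2, RMSEP,
MREP).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import KFold

__all__ = [
    "ClassReport",
    "RegReport",
    "classification_report",
    "regression_report",
    "cross_validated_report",
]


@dataclass
class ClassReport:
    """Support-weighted multiclass metrics with the full confusion matrix."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: pd.DataFrame  # index: class; columns TP/TN/FP/FN/precision/recall/f1/support
    confusion: np.ndarray
    classes: list

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
        }

    def confusion_frame(self) -> pd.DataFrame:
        labels = [str(c) for c in self.classes]
        return pd.DataFrame(self.confusion, index=labels, columns=labels)


@dataclass
class RegReport:
    """Calibration statistics; ``context`` is 'cv' or 'prediction'."""

    r2: float
    rmse: float
    mre: float
    context: str = "prediction"

    def to_dict(self) -> dict:
        return asdict(self)


def classification_report(y_true, y_pred, labels=None) -> ClassReport:
    """Confusion matrix plus weighted accuracy/precision/recall/F1.

    ``labels`` fixes the class order (and the confusion-matrix size) when
    some classes are absent from ``y_true``; by default the sorted union
    of observed labels is used.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("empty input")
    classes = (
        np.asarray(labels) if labels is not None
        else np.unique(np.concatenate([y_true, y_pred]))
    )
    cm = _sk_confusion(y_true, y_pred, labels=classes)
    total = cm.sum()
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn
    support = cm.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(2 * tp + fp + fn > 0, 2 * tp / (2 * tp + fp + fn), 0.0)
    weights = support / support.sum()
    per_class = pd.DataFrame(
        {
            "TP": tp.astype(int),
            "TN": tn.astype(int),
            "FP": fp.astype(int),
            "FN": fn.astype(int),
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": support.astype(int),
        },
        index=[str(c) for c in classes],
    )
    return ClassReport(
        accuracy=float(tp.sum() / total),
        precision=float(np.sum(weights * precision)),
        recall=float(np.sum(weights * recall)),
        f1=float(np.sum(weights * f1)),
        per_class=per_class,
        confusion=cm,
        classes=list(classes),
    )


def report_from_confusion(confusion, classes) -> ClassReport:
    """Rebuild a :class:`ClassReport` from a confusion matrix alone.

    All aggregate metrics are functions of the matrix, so this inverts the
    report -> confusion projection exactly.
    """
    cm = np.asarray(confusion, dtype=int)
    classes = list(classes)
    y_true, y_pred = [], []
    for i, ci in enumerate(classes):
        for j, cj in enumerate(classes):
            y_true.extend([ci] * cm[i, j])
            y_pred.extend([cj] * cm[i, j])
    return classification_report(np.asarray(y_true), np.asarray(y_pred), labels=classes)


def regression_report(y_true, y_pred, context: str = "prediction") -> RegReport:
    """R^2, RMSE and mean relative error of predictions against references."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("empty input")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("y_true has zero variance; R^2 undefined")
    if np.any(y_true <= 0):
        raise ValueError("mean relative error requires strictly positive references")
    resid = y_pred - y_true
    return RegReport(
        r2=1.0 - float(np.sum(resid**2)) / ss_tot,
        rmse=float(np.sqrt(np.mean(resid**2))),
        mre=float(np.mean(np.abs(resid) / y_true)),
        context=context,
    )


def cross_validated_report(
    model_factory: Callable[[], object],
    X_train: np.ndarray,
    y_train: np.ndarray,
    folds: int = 5,
    seed: int = 0,
) -> RegReport:
    """Out-of-fold regression report on the training set.

    A fresh model from ``model_factory`` is fit per fold; out-of-fold
    predictions are assembled over all samples and reported once with
    context ``cv`` (i.e. Rv2 / RMSECV / MRECV).  Deterministic given seed.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.full(len(y_train), np.nan)
    for tr, te in splitter.split(X_train):
        model = model_factory()
        model.fit(X_train[tr], y_train[tr])
        oof[te] = np.asarray(model.predict(X_train[te])).ravel()
    if np.isnan(oof).any():
        raise RuntimeError("a fold produced no predictions")
    return regression_report(y_train, oof, context="cv")
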