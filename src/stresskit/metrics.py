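"""Confusion-matrix-based evaluation.

Implements accuracy, per-class precision/recall/F1 (one-vs-rest reduction),
the Matthews correlation coefficient in its binary form
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
and its multiclass generalisation (the Rk statistic: the Pearson correlation
between one-hot true and predicted assignments, which reduces to the binary
form at C = 2), and one-vs-rest ROC AUC via the Mann-Whitney rank statistic
with midranks for ties.

Conventions: a zero factor in an MCC denominator yields MCC = 0; metrics
undefined for an empty class are reported as NaN and excluded from macro
averages with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.stats import rankdata

from .errors import ContractError, ParameterError


@dataclass
class ConfusionMatrix:
    """Counts[i, j] = number of samples with true class i predicted as j."""

    counts: np.ndarray
    labels: np.ndarray = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ParameterError("confusion matrix must be square")
        if np.any(self.counts < 0) or np.any(self.counts != self.counts.astype(int)):
            raise ParameterError("confusion matrix entries must be non-negative integers")
        self.counts = self.counts.astype(np.int64)
        if self.labels is None:
            self.labels = np.arange(self.counts.shape[0])

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ContractError("y_true and y_pred must have equal length")
    if y_true.size and (
        y_true.min() < 0 or y_true.max() >= n_classes or y_pred.min() < 0 or y_pred.max() >= n_classes
    ):
        raise ContractError(f"labels must lie in 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts=counts)


def _one_vs_rest(cm: ConfusionMatrix, c: int):
    counts = cm.counts
    tp = counts[c, c]
    fn = counts[c].sum() - tp
    fp = counts[:, c].sum() - tp
    tn = cm.total - tp - fn - fp
    return int(tp), int(tn), int(fp), int(fn)


def basic_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy plus per-class and macro precision/recall/F1.

    Multiclass accuracy is trace/total (the one-vs-rest binary accuracy
    formula averaged over classes is reported separately as ``ovr_accuracy``).
    """
    if cm.total == 0:
        raise ParameterError("empty confusion matrix")
    C = cm.n_classes
    precision = np.full(C, np.nan)
    recall = np.full(C, np.nan)
    f1 = np.full(C, np.nan)
    ovr_acc = np.empty(C)
    for c in range(C):
        tp, tn, fp, fn = _one_vs_rest(cm, c)
        ovr_acc[c] = (tp + tn) / (tp + tn + fp + fn)
        if tp + fp > 0:
            precision[c] = tp / (tp + fp)
        if tp + fn > 0:
            recall[c] = tp / (tp + fn)
        else:
            warnings.warn(f"class {c} absent from truth; recall undefined", stacklevel=2)
        if np.isfinite(precision[c]) and np.isfinite(recall[c]) and precision[c] + recall[c] > 0:
            f1[c] = 2 * precision[c] * recall[c] / (precision[c] + recall[c])
    return {
        "accuracy": float(np.trace(cm.counts) / cm.total),
        "ovr_accuracy": float(ovr_acc.mean()),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "macro_precision": float(np.nanmean(precision)),
        "macro_recall": float(np.nanmean(recall)),
        "macro_f1": float(np.nanmean(f1)),
    }


def mcc_binary(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient for a 2x2 matrix (literal formula)."""
    if cm.n_classes != 2:
        raise ParameterError("mcc_binary requires a 2x2 matrix")
    tp, tn, fp, fn = _one_vs_rest(cm, 1)
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(den))


def mcc_multiclass(cm: ConfusionMatrix) -> float:
    """Generalised (Rk) MCC; equals the binary formula at C = 2.

    Returns NaN when both truth and prediction are concentrated in a single
    class (undefined); 0 when only one side is degenerate.
    """
    counts = cm.counts.astype(float)
    t = counts.sum(axis=1)  # true-class totals
    p = counts.sum(axis=0)  # predicted-class totals
    n = counts.sum()
    if (t > 0).sum() <= 1 and (p > 0).sum() <= 1:
        return float("nan")
    cov = np.trace(counts) * n - t @ p
    den = np.sqrt(n**2 - p @ p) * np.sqrt(n**2 - t @ t)
    if den == 0:
        return 0.0
    return float(cov / den)


def per_class_mcc(cm: ConfusionMatrix) -> np.ndarray:
    """Binary one-vs-rest MCC for each class."""
    out = np.empty(cm.n_classes)
    for c in range(cm.n_classes):
        tp, tn, fp, fn = _one_vs_rest(cm, c)
        two = ConfusionMatrix(counts=np.array([[tn, fp], [fn, tp]]))
        out[c] = mcc_binary(two)
    return out


def _auc_rank(scores: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney AUC with midranks for ties."""
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_auc(y_true, probabilities) -> dict:
    """Per-class one-vs-rest AUC and the micro-average AUC.

    The micro average pools every (sample, class) score against the binarised
    truth.  Classes absent from ``y_true`` get AUC = NaN.
    """
    y_true = np.asarray(y_true, dtype=int)
    proba = np.atleast_2d(np.asarray(probabilities, dtype=float))
    if proba.shape[0] != y_true.size:
        raise ContractError("probability rows must match y_true length")
    if not np.allclose(proba.sum(axis=1), 1.0, atol=1e-6):
        raise ContractError("probability rows must sum to 1")
    C = proba.shape[1]
    per_class = {}
    for c in range(C):
        per_class[c] = _auc_rank(proba[:, c], y_true == c)
    onehot = np.zeros_like(proba, dtype=bool)
    onehot[np.arange(y_true.size), y_true] = True
    micro = _auc_rank(proba.ravel(), onehot.ravel())
    return {"per_class": per_class, "micro": micro}


@dataclass
class MetricsReport:
    """Full evaluation bundle for one classifier on one split."""

    confusion: ConfusionMatrix
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    mcc: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    per_class_f1: np.ndarray
    per_class_mcc: np.ndarray
    auc_per_class: Optional[Dict[int, float]] = None
    auc_micro: Optional[float] = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(v):
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

        return {
            "accuracy": self.accuracy,
            "macro_precision": clean(self.macro_precision),
            "macro_recall": clean(self.macro_recall),
            "macro_f1": clean(self.macro_f1),
            "mcc": clean(self.mcc),
            "per_class": {
                str(c): {
                    "precision": clean(self.per_class_precision[c]),
                    "recall": clean(self.per_class_recall[c]),
                    "f1": clean(self.per_class_f1[c]),
                    "mcc": clean(self.per_class_mcc[c]),
                    "auc": clean(self.auc_per_class[c]) if self.auc_per_class else None,
                }
                for c in range(self.confusion.n_classes)
            },
            "auc_micro": clean(self.auc_micro),
            "confusion_matrix": self.confusion.counts.tolist(),
            **self.extra,
        }


def evaluate_predictions(y_true, y_pred, n_classes: int, probabilities=None) -> MetricsReport:
    """One-call evaluation: confusion matrix, rates, MCC, and (optionally) AUC."""
    cm = confusion_matrix(y_true, y_pred, n_classes)
    basics = basic_metrics(cm)
    auc = roc_auc(y_true, probabilities) if probabilities is not None else None
    return MetricsReport(
        confusion=cm,
        accuracy=basics["accuracy"],
        macro_precision=basics["macro_precision"],
        macro_recall=basics["macro_recall"],
        macro_f1=basics["macro_f1"],
        mcc=mcc_multiclass(cm),
        per_class_precision=basics["precision"],
        per_class_recall=basics["recall"],
        per_class_f1=basics["f1"],
        per_class_mcc=per_class_mcc(cm),
        auc_per_class=auc["per_class"] if auc else None,
        auc_micro=auc["micro"] if auc else None,
    )
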