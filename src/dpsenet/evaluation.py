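"""Classification metrics: confusion matrix, one-vs-rest P/R/F1, ROC/AUC.

Per-class scores follow the one-vs-rest reduction of the confusion matrix:
TP is the diagonal cell, FP the rest of the column, FN the rest of the row,
TN everything else; precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their
harmonic mean, accuracy = trace/total. Macro values are unweighted class
means (for balanced classes macro and weighted averaging coincide). ROC
curves are one-vs-rest threshold sweeps over softmax scores with trapezoidal
AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (K, K) ints; rows = true class, columns = predicted
    class_names: list[str]

    def normalized(self) -> np.ndarray:
        """Row-normalized percentages; rows with no members become NaN."""
        row_sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        empty = row_sums[:, 0] == 0
        if empty.any():
            warnings.warn(
                f"classes absent from y_true have undefined rows: "
                f"{[self.class_names[i] for i in np.flatnonzero(empty)]}")
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.counts / row_sums


@dataclass
class MetricsReport:
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": {
                name: {"precision": float(self.precision[i]),
                       "recall": float(self.recall[i]),
                       "f1": float(self.f1[i]),
                       "tp": int(self.tp[i]), "tn": int(self.tn[i]),
                       "fp": int(self.fp[i]), "fn": int(self.fn[i])}
                for i, name in enumerate(self.class_names or
                                         [str(i) for i in range(len(self.precision))])
            },
        }


@dataclass
class ROCResult:
    fpr: list[np.ndarray]
    tpr: list[np.ndarray]
    auc: np.ndarray  # per-class, NaN where undefined
    class_names: list[str] = field(default_factory=list)


def confusion(y_true, y_pred, n_classes: int, class_names: list[str] | None = None
              ) -> ConfusionMatrix:
    """counts[i, j] = number of samples with true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.size == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    if y_true.max() >= n_classes or y_pred.max() >= n_classes or min(y_true.min(), y_pred.min()) < 0:
        raise ValueError(f"labels out of range for {n_classes} classes")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts=counts,
                           class_names=class_names or [str(i) for i in range(n_classes)])


def _safe_div(num, den, what):
    out = np.zeros_like(num, dtype=float)
    zero = den == 0
    if zero.any():
        warnings.warn(f"zero denominator in {what} for classes {np.flatnonzero(zero).tolist()}; "
                      "reporting 0")
    np.divide(num, den, out=out, where=~zero)
    return out


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, per-class and macro precision/recall/F1 from the matrix."""
    counts = np.asarray(cm.counts)
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero confusion matrix")
    tp = np.diag(counts).astype(np.int64)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    tn = total - tp - fp - fn
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1")
    return MetricsReport(
        accuracy=float(tp.sum() / total),
        precision=precision, recall=recall, f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        tp=tp, tn=tn, fp=fp, fn=fn,
        class_names=list(cm.class_names),
    )


def roc_auc(y_true, scores, class_names: list[str] | None = None) -> ROCResult:
    """One-vs-rest ROC per class from an N×K score matrix, trapezoidal AUC."""
    y_true = np.asarray(y_true, dtype=np.int64)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n, k = scores.shape
    if len(y_true) != n:
        raise ValueError("y_true and scores disagree in length")
    fprs, tprs, aucs = [], [], []
    for c in range(k):
        pos = y_true == c
        if pos.all() or not pos.any():
            warnings.warn(f"class {c} has no positives or no negatives; AUC undefined")
            fprs.append(np.array([0.0, 1.0]))
            tprs.append(np.array([0.0, 1.0]))
            aucs.append(np.nan)
            continue
        fpr, tpr, _ = _roc_curve(pos.astype(int), scores[:, c])
        fprs.append(fpr)
        tprs.append(tpr)
        aucs.append(_trapezoid_auc(fpr, tpr))
    return ROCResult(fpr=fprs, tpr=tprs, auc=np.asarray(aucs),
                     class_names=class_names or [str(i) for i in range(k)])


def evaluate_model(model, images, labels, class_names=None, batch_size: int = 32):
    """Predict and compute (ConfusionMatrix, MetricsReport, ROCResult)."""
    probs = model.predict_proba(images, batch_size=batch_size)
    preds = probs.argmax(axis=1)
    cm = confusion(labels, preds, model.config.n_classes, class_names)
    return cm, metrics(cm), roc_auc(labels, probs, class_names)
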