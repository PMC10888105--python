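"""Confusion-matrix bookkeeping and evaluation metrics.

Conventions: confusion-matrix rows are the actual classes and columns the
predicted classes.  Per-class counts come from the one-vs-rest view of the
matrix (tp on the diagonal, fn along the rest of the row, fp along the rest
of the column).  Precision, recall and F1 follow the usual formulas

    precision = TP / (TP + FP)      recall = TP / (TP + FN)
    F1 = 2 * precision * recall / (precision + recall)

with the 0/0 cases returning 0 (logged).  Multiclass summaries are macro
averages — the unweighted mean over classes — and the averaging scheme is
recorded in every report to avoid silent mismatch with weighted schemes.
AUC is the tie-corrected Mann-Whitney ranking statistic per class in a
one-vs-rest view, macro-averaged over classes that have both positives and
negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .ensemble import predict_labels, validate_labels
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C counts; rows = actual class, columns = predicted class."""

    counts: np.ndarray
    class_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValidationError(f"counts must be square, got shape {counts.shape}")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValidationError("counts must be non-negative integers")
        object.__setattr__(self, "counts", counts)
        if self.class_names is not None:
            names = tuple(str(s) for s in self.class_names)
            if len(names) != counts.shape[0]:
                raise ValidationError(
                    f"{len(names)} class names for {counts.shape[0]} classes"
                )
            object.__setattr__(self, "class_names", names)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ClassCounts:
    """One-vs-rest TP/FP/FN/TN counts for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("counts must be non-negative")


@dataclass(frozen=True)
class MetricsReport:
    """Full evaluation summary, serializable to a plain dict."""

    accuracy: float
    precision_per_class: np.ndarray
    recall_per_class: np.ndarray
    f1_per_class: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_auc_ovr: float
    confusion_matrix: ConfusionMatrix
    averaging: str = field(default="macro")

    def to_dict(self) -> dict:
        cm = self.confusion_matrix
        return {
            "averaging": self.averaging,
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "macro_auc_ovr": self.macro_auc_ovr,
            "per_class": {
                "precision": list(self.precision_per_class),
                "recall": list(self.recall_per_class),
                "f1": list(self.f1_per_class),
            },
            "confusion_matrix": {
                "rows_are": "actual",
                "columns_are": "predicted",
                "counts": cm.counts.tolist(),
                "class_names": list(cm.class_names) if cm.class_names else None,
            },
        }


def confusion(
    labels: np.ndarray,
    predicted: np.ndarray,
    n_classes: int,
    class_names: tuple[str, ...] | None = None,
) -> ConfusionMatrix:
    """Count (actual, predicted) pairs into a C x C matrix."""
    y = validate_labels(labels, n_classes)
    p = validate_labels(predicted, n_classes)
    if y.size != p.size:
        raise ValidationError(f"{y.size} labels vs {p.size} predictions")
    counts = np.bincount(y * n_classes + p, minlength=n_classes * n_classes)
    return ConfusionMatrix(counts.reshape(n_classes, n_classes), class_names)


def class_counts(cm: ConfusionMatrix, k: int) -> ClassCounts:
    """One-vs-rest counts for class ``k`` read off the confusion matrix."""
    if not 0 <= k < cm.n_classes:
        raise ValidationError(f"class {k} out of range for C={cm.n_classes}")
    counts = cm.counts
    tp = int(counts[k, k])
    fn = int(counts[k].sum()) - tp
    fp = int(counts[:, k].sum()) - tp
    tn = cm.n_samples - tp - fn - fp
    return ClassCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correct predictions: trace over total."""
    n = cm.n_samples
    if n == 0:
        raise ValidationError("empty confusion matrix")
    return float(np.trace(cm.counts)) / n


def precision(counts: ClassCounts) -> float:
    denom = counts.tp + counts.fp
    if denom == 0:
        logger.warning("precision 0/0 (no predicted positives); returning 0")
        return 0.0
    return counts.tp / denom


def recall(counts: ClassCounts) -> float:
    denom = counts.tp + counts.fn
    if denom == 0:
        logger.warning("recall 0/0 (no actual positives); returning 0")
        return 0.0
    return counts.tp / denom


def f1(counts: ClassCounts) -> float:
    p, r = precision(counts), recall(counts)
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def _auc_binary(pos_mask: np.ndarray, scores: np.ndarray) -> float:
    # tie-corrected Mann-Whitney: mean rank of positives vs expectation
    ranks = rankdata(scores)
    n_pos = int(pos_mask.sum())
    n_neg = pos_mask.size - n_pos
    u = ranks[pos_mask].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_ovr(labels: np.ndarray, probs: np.ndarray) -> float:
    """Macro one-vs-rest AUC from the per-class probability columns.

    Classes lacking either positives or negatives are skipped with a
    warning; if no class is scoreable the AUC is undefined and an error is
    raised.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.size == 0:
        raise ValidationError(f"probs must be a non-empty (N, C) matrix, got {probs.shape}")
    n, c = probs.shape
    y = validate_labels(labels, c, n)
    per_class = []
    for k in range(c):
        pos = y == k
        n_pos = int(pos.sum())
        if n_pos == 0 or n_pos == n:
            logger.warning("class %d has no %s; skipped in AUC", k, "positives" if n_pos == 0 else "negatives")
            continue
        per_class.append(_auc_binary(pos, probs[:, k]))
    if not per_class:
        raise ValidationError("AUC undefined: no class has both positives and negatives")
    return float(np.mean(per_class))


def report(
    labels: np.ndarray,
    probs: np.ndarray,
    class_names: tuple[str, ...] | None = None,
) -> MetricsReport:
    """Assemble the full metric suite from one predicted-label pass."""
    probs = np.asarray(probs, dtype=float)
    predicted = predict_labels(probs)
    c = probs.shape[1]
    cm = confusion(labels, predicted, c, class_names)
    per = [class_counts(cm, k) for k in range(c)]
    prec = np.array([precision(cc) for cc in per])
    rec = np.array([recall(cc) for cc in per])
    f1s = np.array([f1(cc) for cc in per])
    return MetricsReport(
        accuracy=accuracy(cm),
        precision_per_class=prec,
        recall_per_class=rec,
        f1_per_class=f1s,
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1s.mean()),
        macro_auc_ovr=auc_ovr(labels, probs),
        confusion_matrix=cm,
    )
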