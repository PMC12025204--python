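"""Confusion-matrix metrics: accuracy, sensitivity/recall, specificity,
precision, F1 — per class and macro/micro/weighted averaged.

Rows of the confusion matrix are true classes, columns predicted classes.
A zero denominator (e.g. precision of a never-predicted class) yields 0 and
sets a warning flag rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (K, K) ints, rows = true, cols = predicted

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise DataError(f"confusion matrix must be square, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise DataError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]


@dataclass
class MetricsReport:
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray  # sensitivity
    specificity: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_specificity: float
    macro_f1: float
    micro_f1: float
    weighted_f1: float
    support: np.ndarray
    zero_division: bool = False
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_specificity": self.macro_specificity,
            "macro_f1": self.macro_f1,
            "micro_f1": self.micro_f1,
            "weighted_f1": self.weighted_f1,
            "per_class": {
                "precision": self.precision.tolist(),
                "recall": self.recall.tolist(),
                "specificity": self.specificity.tolist(),
                "f1": self.f1.tolist(),
                "support": self.support.tolist(),
            },
        }

    def to_text(self, class_names=None) -> str:
        k = len(self.precision)
        names = class_names or [f"class_{i}" for i in range(k)]
        lines = ["class\tprecision\trecall\tspecificity\tf1\tsupport"]
        for i in range(k):
            lines.append(
                f"{names[i]}\t{self.precision[i]:.4f}\t{self.recall[i]:.4f}"
                f"\t{self.specificity[i]:.4f}\t{self.f1[i]:.4f}\t{self.support[i]}"
            )
        lines.append(
            f"macro\t{self.macro_precision:.4f}\t{self.macro_recall:.4f}"
            f"\t{self.macro_specificity:.4f}\t{self.macro_f1:.4f}\t{self.support.sum()}"
        )
        lines.append(f"accuracy\t{self.accuracy:.4f}")
        return "\n".join(lines)


def confusion(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise DataError(
            f"label vectors differ in length: {y_true.shape} vs {y_pred.shape}"
        )
    if len(y_true) and (
        y_true.min() < 0
        or y_pred.min() < 0
        or y_true.max() >= n_classes
        or y_pred.max() >= n_classes
    ):
        raise DataError(f"labels must lie in 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return ConfusionMatrix(cm)


def _safe_div(num: np.ndarray, den: np.ndarray):
    zero = den == 0
    out = np.where(zero, 0.0, num / np.where(zero, 1, den))
    return out, bool(zero.any())


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class and averaged metrics from a confusion matrix."""
    c = cm.counts
    total = cm.total
    if total == 0:
        raise DataError("empty confusion matrix")
    tp = np.diag(c).astype(float)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    tn = total - tp - fp - fn

    precision, z1 = _safe_div(tp, tp + fp)
    recall, z2 = _safe_div(tp, tp + fn)
    specificity, z3 = _safe_div(tn, tn + fp)
    f1, z4 = _safe_div(2 * precision * recall, precision + recall)
    support = c.sum(axis=1)

    micro_tp, micro_fp, micro_fn = tp.sum(), fp.sum(), fn.sum()
    micro_f1 = 2 * micro_tp / max(2 * micro_tp + micro_fp + micro_fn, 1)
    weights = support / total

    return MetricsReport(
        accuracy=float(tp.sum() / total),
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_specificity=float(specificity.mean()),
        macro_f1=float(f1.mean()),
        micro_f1=float(micro_f1),
        weighted_f1=float((weights * f1).sum()),
        support=support,
        zero_division=z1 or z2 or z3 or z4,
    )
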