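"""Utility metrics: accuracy, F1 and parameter counts.

Binary tasks use the textbook confusion-count formulas
``accuracy = (TP + TN) / (TP + TN + FP + FN)`` and
``F1 = 2 TP / (2 TP + FP + FN)``.  Multiclass tasks reduce a C x C
confusion table: accuracy is trace over total; F1 is the macro average
of per-class one-vs-rest F1 (the weighted average is reported
alongside).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import LabeledDataset

__all__ = [
    "ConfusionCounts",
    "confusion_table",
    "accuracy",
    "f1",
    "count_parameters",
    "evaluate_model",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts (use :func:`confusion_table` for C > 2)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_table(y_true, y_pred, num_classes: int) -> np.ndarray:
    """C x C table; rows are true classes, columns predictions."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    table = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(table, (y_true, y_pred), 1)
    return table


def accuracy(counts) -> float:
    """Fraction of correct predictions."""
    if isinstance(counts, ConfusionCounts):
        if counts.total == 0:
            raise ValueError("no samples evaluated")
        return (counts.tp + counts.tn) / counts.total
    table = np.asarray(counts)
    total = table.sum()
    if total == 0:
        raise ValueError("no samples evaluated")
    return float(np.trace(table) / total)


def _binary_f1(tp: float, fp: float, fn: float) -> float:
    denom = 2 * tp + fp + fn
    if denom == 0:
        warnings.warn("F1 undefined (no positives anywhere); defining it as 0")
        return 0.0
    return 2 * tp / denom


def f1(counts, average: str = "macro") -> float:
    """F1 score.

    Binary :class:`ConfusionCounts` use the direct formula; a multiclass
    confusion table is reduced one-vs-rest and averaged (``macro`` or
    ``weighted``).
    """
    if isinstance(counts, ConfusionCounts):
        return _binary_f1(counts.tp, counts.fp, counts.fn)
    table = np.asarray(counts, dtype=np.float64)
    C = table.shape[0]
    per_class = np.empty(C)
    for c in range(C):
        tp = table[c, c]
        fp = table[:, c].sum() - tp
        fn = table[c, :].sum() - tp
        per_class[c] = _binary_f1(tp, fp, fn)
    if average == "macro":
        return float(per_class.mean())
    if average == "weighted":
        support = table.sum(axis=1)
        if support.sum() == 0:
            raise ValueError("empty confusion table")
        return float((per_class * support).sum() / support.sum())
    raise ValueError(f"unknown average {average!r}")


def count_parameters(model) -> int:
    """Number of trainable parameter elements."""
    return int(model.parameter_count)


def evaluate_model(model, data: LabeledDataset, batch_size: int = 256) -> dict:
    """Accuracy plus macro and weighted F1 on a labeled dataset."""
    if len(data) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    preds = np.concatenate([
        model.predict_proba(data.features[s : s + batch_size]).argmax(axis=1)
        for s in range(0, len(data), batch_size)
    ])
    table = confusion_table(data.labels, preds, data.num_classes)
    return {
        "accuracy": accuracy(table),
        "f1_macro": f1(table, "macro"),
        "f1_weighted": f1(table, "weighted"),
        "n": len(data),
    }
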