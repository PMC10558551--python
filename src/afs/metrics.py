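"""Per-sample membership signals: correctness, confidence, entropy.

A model that has memorised a sample tends to (i) classify it correctly,
(ii) assign high probability to its true class, and (iii) produce a
low-entropy output distribution.  These three signals per sample are the
raw material for threshold calibration and the dataset-level audit.

Entropy uses the natural logarithm, so it lies in ``[0, ln C]``; the
member direction is "small" (thresholds compare with ``<=``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LabeledDataset

__all__ = [
    "correctness",
    "true_label_confidence",
    "prediction_entropy",
    "MetricMatrix",
    "metric_matrix",
]

METRICS = ("correctness", "confidence", "entropy")


def _check_row(prob_row: np.ndarray) -> np.ndarray:
    p = np.asarray(prob_row, dtype=np.float64)
    if (p < 0).any():
        raise ValueError("probability vector has negative entries")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError(f"probability vector sums to {p.sum()}, not 1")
    return p


def _check_label(y: int, C: int) -> int:
    y = int(y)
    if not 0 <= y < C:
        raise ValueError(f"label {y} outside 0..{C - 1}")
    return y


def correctness(prob_row, y) -> int:
    """1 iff the arg-max class equals ``y`` (ties -> lowest class index)."""
    p = _check_row(prob_row)
    y = _check_label(y, len(p))
    return int(int(np.argmax(p)) == y)


def true_label_confidence(prob_row, y) -> float:
    """Probability assigned to the true class."""
    p = _check_row(prob_row)
    return float(p[_check_label(y, len(p))])


def prediction_entropy(prob_row) -> float:
    """Shannon entropy ``-sum p ln p`` (0 log 0 := 0) of the prediction."""
    p = _check_row(prob_row)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


@dataclass(frozen=True)
class MetricMatrix:
    """Per-sample metric scores for one (model, dataset) pair."""

    ids: np.ndarray
    labels: np.ndarray
    correctness: np.ndarray
    confidence: np.ndarray
    entropy: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        for name in ("labels", "correctness", "confidence", "entropy"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} has wrong length")
        if ((self.confidence < 0) | (self.confidence > 1)).any():
            raise ValueError("confidence outside [0, 1]")
        if (self.entropy < -1e-12).any():
            raise ValueError("negative entropy")

    def __len__(self) -> int:
        return len(self.ids)

    def scores(self, metric: str) -> np.ndarray:
        if metric not in METRICS:
            raise KeyError(f"unknown metric {metric!r}")
        return getattr(self, metric)


def metric_matrix(model, data: LabeledDataset, batch_size: int = 256) -> MetricMatrix:
    """Score every sample of ``data`` under ``model`` (order preserved)."""
    if model.num_classes != data.num_classes:
        raise ValueError(
            f"model has {model.num_classes} classes, dataset declares {data.num_classes}"
        )
    probs = np.vstack([
        model.predict_proba(data.features[s : s + batch_size])
        for s in range(0, len(data), batch_size)
    ]) if len(data) else np.empty((0, model.num_classes))
    probs = np.asarray(probs, dtype=np.float64)
    probs = probs / probs.sum(axis=1, keepdims=True)  # guard fp drift
    n = len(data)
    idx = np.arange(n)
    corr = (probs.argmax(axis=1) == data.labels).astype(np.int8)
    conf = probs[idx, data.labels]
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(probs > 0, np.log(np.where(probs > 0, probs, 1.0)), 0.0)
    ent = -(probs * logp).sum(axis=1)
    return MetricMatrix(data.ids.copy(), data.labels.copy(), corr, np.clip(conf, 0, 1),
                        np.maximum(ent, 0.0))
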