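"""Threshold calibration against a shadow ("calibration") model.

The calibration dataset is disjoint from the target model's training
data.  Half of it trains a calibration model of known membership; the
calibration model's metric scores on its own training half (members)
versus the other half (non-members) then yield, per metric and per
class, the decision threshold maximising balanced accuracy
``(TPR(t) + TNR(t)) / 2``.

Candidate thresholds are the midpoints between consecutive sorted unique
pooled scores plus one sentinel below the minimum and one above the
maximum; among equally good candidates the smallest wins.  Classes with
fewer than ``min_per_side`` calibration samples on either side fall back
to a pooled (class-agnostic) threshold.  Correctness is already binary
and keeps a fixed threshold of 0.5 with member direction ">=".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import LabeledDataset
from .metrics import METRICS, MetricMatrix, metric_matrix
from .models import ModelSpec, build_model
from .training import TrainConfig, train_supervised

__all__ = [
    "DIRECTIONS",
    "ThresholdSet",
    "balanced_accuracy",
    "best_threshold",
    "infer_thresholds",
    "train_calibration_model",
    "calibrate",
]

#: member side per metric: members score high on correctness/confidence,
#: low on entropy.
DIRECTIONS = {"correctness": "ge", "confidence": "ge", "entropy": "le"}


def _member_side(scores: np.ndarray, t: float, direction: str) -> np.ndarray:
    return scores >= t if direction == "ge" else scores <= t


def balanced_accuracy(t, member_scores, nonmember_scores, direction) -> float:
    """(TPR + TNR) / 2 at threshold ``t``.

    TPR is the fraction of member scores on the member side of ``t``;
    TNR the fraction of non-member scores strictly on the other side.
    """
    if direction not in ("ge", "le"):
        raise ValueError(f"direction must be 'ge' or 'le', got {direction!r}")
    m = np.asarray(member_scores, dtype=np.float64)
    nm = np.asarray(nonmember_scores, dtype=np.float64)
    if len(m) == 0 or len(nm) == 0:
        raise ValueError("member and non-member score lists must be non-empty")
    tpr = _member_side(m, t, direction).mean()
    tnr = 1.0 - _member_side(nm, t, direction).mean()
    return float((tpr + tnr) / 2.0)


def _candidates(pooled: np.ndarray) -> np.ndarray:
    u = np.unique(pooled)
    mids = (u[:-1] + u[1:]) / 2.0 if len(u) > 1 else np.empty(0)
    return np.concatenate([[u[0] - 1.0], mids, [u[-1] + 1.0]])


def best_threshold(member_scores, nonmember_scores, direction) -> tuple[float, float]:
    """Exhaustive search over candidate thresholds.

    Returns ``(threshold, balanced_accuracy)``; the smallest maximiser
    wins ties.
    """
    m = np.asarray(member_scores, dtype=np.float64)
    nm = np.asarray(nonmember_scores, dtype=np.float64)
    if len(m) == 0 or len(nm) == 0:
        raise ValueError("member and non-member score lists must be non-empty")
    cand = _candidates(np.concatenate([m, nm]))
    ms = np.sort(m)
    nms = np.sort(nm)
    # integer confusion counts keep the comparison exact under ties
    if direction == "ge":
        tp = len(ms) - np.searchsorted(ms, cand, side="left")
        tn = np.searchsorted(nms, cand, side="left")
    else:
        tp = np.searchsorted(ms, cand, side="right")
        tn = len(nms) - np.searchsorted(nms, cand, side="right")
    score = tp * len(nms) + tn * len(ms)
    i = int(np.argmax(score))  # first (= smallest candidate) maximiser
    return float(cand[i]), float(score[i] / (2 * len(ms) * len(nms)))


@dataclass(frozen=True)
class ThresholdSet:
    """Per-metric, per-class thresholds with pooled fallbacks."""

    per_class: dict            # metric -> {class index -> threshold}
    fallback: dict             # metric -> threshold
    num_classes: int
    min_per_side: int = 5
    provenance: dict = field(default_factory=dict)

    def resolve(self, metric: str, y: int) -> tuple[float, str]:
        """Threshold and member direction for (metric, class)."""
        if metric not in METRICS:
            raise KeyError(f"unknown metric {metric!r}")
        if not 0 <= int(y) < self.num_classes:
            raise ValueError(f"class {y} outside 0..{self.num_classes - 1}")
        t = self.per_class.get(metric, {}).get(int(y), self.fallback.get(metric))
        if t is None:
            raise ValueError(f"no threshold resolvable for ({metric}, class {y})")
        return float(t), DIRECTIONS[metric]

    def to_json(self, path=None) -> str:
        payload = {
            "per_class": {m: {str(c): t for c, t in d.items()}
                          for m, d in self.per_class.items()},
            "fallback": self.fallback,
            "directions": DIRECTIONS,
            "num_classes": self.num_classes,
            "min_per_side": self.min_per_side,
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ThresholdSet":
        if isinstance(source, Path) or (isinstance(source, str) and not source.lstrip().startswith("{")):
            source = Path(source).read_text()
        d = json.loads(source)
        return cls(
            per_class={m: {int(c): t for c, t in v.items()} for m, v in d["per_class"].items()},
            fallback=d["fallback"],
            num_classes=d["num_classes"],
            min_per_side=d.get("min_per_side", 5),
            provenance=d.get("provenance", {}),
        )


def infer_thresholds(
    member_matrix: MetricMatrix,
    nonmember_matrix: MetricMatrix,
    num_classes: int | None = None,
    min_per_side: int = 5,
) -> ThresholdSet:
    """Per-metric, per-class thresholds maximising balanced accuracy."""
    if len(member_matrix) == 0 or len(nonmember_matrix) == 0:
        raise ValueError("member and non-member matrices must be non-empty")
    if num_classes is None:
        num_classes = int(max(member_matrix.labels.max(), nonmember_matrix.labels.max())) + 1

    per_class: dict = {"confidence": {}, "entropy": {}}
    fallback: dict = {"correctness": 0.5}
    per_class["correctness"] = {}
    for metric in ("confidence", "entropy"):
        direction = DIRECTIONS[metric]
        m_all = member_matrix.scores(metric)
        nm_all = nonmember_matrix.scores(metric)
        fallback[metric], _ = best_threshold(m_all, nm_all, direction)
        for y in range(num_classes):
            m = m_all[member_matrix.labels == y]
            nm = nm_all[nonmember_matrix.labels == y]
            if len(m) >= min_per_side and len(nm) >= min_per_side:
                per_class[metric][y], _ = best_threshold(m, nm, direction)
    return ThresholdSet(per_class, fallback, num_classes, min_per_side)


def train_calibration_model(
    spec: ModelSpec,
    cal_train: LabeledDataset,
    config: TrainConfig | None = None,
    seed: int = 0,
):
    """Train the shadow model on the member half of the calibration data."""
    if len(cal_train) == 0:
        raise ValueError("calibration training set is empty")
    model = build_model(spec, seed)
    return train_supervised(model, cal_train, config or TrainConfig(), seed)


def calibrate(
    spec: ModelSpec,
    calibration: LabeledDataset,
    config: TrainConfig | None = None,
    seed: int = 0,
    min_per_side: int = 5,
) -> ThresholdSet:
    """Full calibration: 50/50 split, shadow training, threshold search.

    The first half (members) trains the calibration model; metric scores
    on it versus the held-back half (non-members) drive the threshold
    search.  Deterministic for fixed ``seed``.
    """
    if len(calibration) < 2:
        raise ValueError("calibration dataset needs at least 2 samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(calibration))
    half = len(calibration) // 2
    cal_train = calibration.take(perm[:half])
    cal_test = calibration.take(perm[half:])
    model = train_calibration_model(spec, cal_train, config, seed)
    member = metric_matrix(model, cal_train)
    nonmember = metric_matrix(model, cal_test)
    ts = infer_thresholds(member, nonmember, calibration.num_classes, min_per_side)
    return ThresholdSet(
        ts.per_class, ts.fallback, ts.num_classes, ts.min_per_side,
        provenance={"seed": seed, "calibration_model": model.fingerprint,
                    "cal_train_n": len(cal_train), "cal_test_n": len(cal_test)},
    )
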