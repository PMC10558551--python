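"""Dataset-level membership auditing.

Per sample, the three calibrated metrics vote by an OR rule: a sample is
deemed a member if it is classified correctly, *or* its true-class
confidence reaches the class threshold, *or* its prediction entropy is
at or below the class threshold.  The resulting 0/1 membership vector is
compared against an all-one vector (what a fully memorised dataset would
look like) with a two-tailed pooled-variance two-sample t-test; the
p-value is the audit verdict.  Large p means "member-like": the test
cannot tell the query votes from all-ones.

Degenerate cases are fixed by convention: a vote vector identical to the
reference gives p = 1; zero pooled variance with unequal means gives
p = 0.  Queries with fewer than 20 samples carry a low-power flag — a
two-sample test on a handful of binary votes has essentially no
resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .calibration import ThresholdSet, calibrate
from .data import LabeledDataset, QueryDataset
from .metrics import MetricMatrix, metric_matrix
from .models import ModelSpec
from .training import TrainConfig

__all__ = [
    "LOW_POWER_N",
    "MembershipVector",
    "AuditResult",
    "sample_membership",
    "membership_votes",
    "audit_pvalue",
    "audit_metric_matrix",
    "audit_dataset",
]

LOW_POWER_N = 20


@dataclass(frozen=True)
class MembershipVector:
    """Per-sample OR-rule votes plus the per-metric breakdown."""

    ids: np.ndarray
    votes: np.ndarray                    # {0,1}, OR of the three columns
    by_metric: dict = field(default_factory=dict)  # metric -> {0,1} array

    def __post_init__(self):
        if len(self.votes) != len(self.ids):
            raise ValueError("vote vector length mismatch")

    def __len__(self) -> int:
        return len(self.votes)

    @property
    def member_fraction(self) -> float:
        return float(np.mean(self.votes)) if len(self.votes) else float("nan")


def sample_membership(metric_row: dict, y: int, thresholds: ThresholdSet) -> int:
    """OR-rule vote for one sample.

    ``metric_row`` maps metric name to its scalar score.  Returns 1 iff
    at least one metric lands on its member side.
    """
    for metric in ("correctness", "confidence", "entropy"):
        t, direction = thresholds.resolve(metric, y)
        s = metric_row[metric]
        if (s >= t) if direction == "ge" else (s <= t):
            return 1
    return 0


def membership_votes(matrix: MetricMatrix, thresholds: ThresholdSet) -> MembershipVector:
    """Vectorised OR-rule votes for a whole metric matrix."""
    n = len(matrix)
    by_metric = {}
    for metric in ("correctness", "confidence", "entropy"):
        scores = matrix.scores(metric).astype(np.float64)
        col = np.empty(n, dtype=np.int8)
        for y in np.unique(matrix.labels):
            t, direction = thresholds.resolve(metric, int(y))
            sel = matrix.labels == y
            hit = scores[sel] >= t if direction == "ge" else scores[sel] <= t
            col[sel] = hit.astype(np.int8)
        by_metric[metric] = col
    votes = (by_metric["correctness"] | by_metric["confidence"] | by_metric["entropy"])
    return MembershipVector(matrix.ids.copy(), votes.astype(np.int8), by_metric)


def audit_pvalue(votes) -> float:
    """Two-tailed pooled two-sample t-test of the votes vs an all-one vector."""
    v = votes.votes if isinstance(votes, MembershipVector) else np.asarray(votes)
    v = np.asarray(v, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty membership vector")
    ones = np.ones_like(v)
    if np.array_equal(v, ones):
        return 1.0
    if v.std(ddof=0) == 0.0:  # unequal means, zero variance on both sides
        return 0.0
    with warnings.catch_warnings():
        # the reference vector is constant by construction; scipy warns
        # about its zero variance but the pooled statistic is well defined
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(v, ones, equal_var=True)
    return float(p)


@dataclass(frozen=True)
class AuditResult:
    p_value: float
    votes: MembershipVector
    alpha: float
    thresholds: ThresholdSet
    low_power: bool

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def member_fraction(self) -> float:
        return self.votes.member_fraction

    @property
    def verdict(self) -> str:
        return "member-like" if self.p_value >= self.alpha else "non-member-like"

    def report(self) -> dict:
        return {
            "p_value": self.p_value,
            "alpha": self.alpha,
            "verdict": self.verdict,
            "n_query": len(self.votes),
            "member_fraction": self.member_fraction,
            "per_metric_vote_rates": {
                m: float(np.mean(c)) for m, c in self.votes.by_metric.items()
            },
            "low_power": self.low_power,
            "thresholds_provenance": self.thresholds.provenance,
        }


def audit_metric_matrix(
    matrix: MetricMatrix, thresholds: ThresholdSet, alpha: float = 0.05
) -> AuditResult:
    """Audit from precomputed metric scores (fixed thresholds)."""
    votes = membership_votes(matrix, thresholds)
    return AuditResult(audit_pvalue(votes), votes, alpha, thresholds,
                       low_power=len(votes) < LOW_POWER_N)


def audit_dataset(
    target,
    query: QueryDataset | LabeledDataset,
    calibration: LabeledDataset,
    spec: ModelSpec | None = None,
    train_config: TrainConfig | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    thresholds: ThresholdSet | None = None,
) -> AuditResult:
    """End-to-end audit of a query dataset against a target model.

    Calibrates thresholds (unless a precomputed ``thresholds`` is
    passed), scores the query under the target model, applies the OR
    rule and computes the dataset p-value.  ``spec`` is the calibration
    model architecture; it defaults to a student-sized MLP matched to
    the data when omitted.
    """
    data = query.data if isinstance(query, QueryDataset) else query
    if len(data) == 0:
        raise ValueError("query dataset is empty")
    if target.num_classes != calibration.num_classes:
        raise ValueError(
            f"target model has {target.num_classes} classes but the "
            f"calibration dataset declares {calibration.num_classes}"
        )
    if thresholds is None:
        if spec is None:
            spec = ModelSpec("mlp", calibration.num_classes,
                             calibration.features.shape[1:])
        thresholds = calibrate(spec, calibration, train_config, seed)
    matrix = metric_matrix(target, data)
    return audit_metric_matrix(matrix, thresholds, alpha)
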