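"""Knowledge purification: audit-guided teacher-student forgetting.

A student is trained from a pre-trained teacher on a fraction ``k`` of
the retain set (training data minus the forget set).  The loss has three
parts::

    total = (1 - a_kd) * hard + a_kd * kd + beta * forget

* ``hard``   — cross-entropy against the true labels on retain batches,
* ``kd``     — temperature-softened distillation against the teacher's
  outputs on the same batches (scaled by T^2 as usual),
* ``forget`` — a uniformity push on forget-set batches: ``ln C`` minus
  the mean prediction entropy, which is zero exactly when the student is
  maximally uncertain on the forget data.

The dataset-level audit p-value on the forget set is piecewise constant
in the parameters, so it cannot be differentiated directly.  The audit
instead acts through a negative-feedback loop: after every epoch the
forget set is audited on the current student with frozen calibrated
thresholds, and the forget weight ``beta`` is multiplied up while the
audit still flags the data as member-like (p above ``target_p``) and
relaxed back toward its initial value once it no longer does.  Training
stops early when the audit has stayed below ``target_p`` for ``patience``
consecutive epochs while held-out accuracy is within ``accuracy_budget``
of the teacher's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audit import audit_metric_matrix
from .calibration import ThresholdSet, calibrate
from .data import LabeledDataset, QueryDataset, retain_set
from .metrics import metric_matrix
from .models import ModelSpec, build_model, softmax
from .training import Adam, TrainConfig, evaluate_accuracy

__all__ = [
    "ForgetConfig",
    "TrainingTrace",
    "soften",
    "kd_loss",
    "forget_loss",
    "total_loss",
    "afs_train",
]


def soften(probs: np.ndarray, T: float) -> np.ndarray:
    """Temperature-soften probability rows (equivalent to softmax(z / T))."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    p = np.asarray(probs, dtype=np.float64) ** (1.0 / T)
    return p / p.sum(axis=-1, keepdims=True)


def kd_loss(student_probs_T: np.ndarray, teacher_probs_T: np.ndarray, T: float) -> float:
    """T^2-scaled KL(teacher || student) averaged over the batch.

    Inputs are already temperature-softened probability rows; zero iff
    they coincide.
    """
    s = np.asarray(student_probs_T, dtype=np.float64)
    t = np.asarray(teacher_probs_T, dtype=np.float64)
    if s.shape != t.shape:
        raise ValueError(f"shape mismatch {s.shape} vs {t.shape}")
    nz = t > 0
    kl = np.where(nz, t * (np.log(np.where(nz, t, 1.0)) - np.log(np.maximum(s, 1e-300))), 0.0)
    return float(T * T * kl.sum(axis=-1).mean())


def forget_loss(student_probs: np.ndarray) -> float:
    """Mean ``ln C - entropy`` over a forget batch (0 iff all rows uniform)."""
    p = np.asarray(student_probs, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty forget batch")
    C = p.shape[-1]
    nz = p > 0
    ent = -np.where(nz, p * np.log(np.where(nz, p, 1.0)), 0.0).sum(axis=-1)
    return float(np.log(C) - ent.mean())


def total_loss(hard: float, kd: float, forget: float, kd_weight: float, beta: float) -> float:
    """(1 - a_kd) * hard + a_kd * kd + beta * forget."""
    return (1.0 - kd_weight) * hard + kd_weight * kd + beta * forget


@dataclass
class ForgetConfig:
    """Knowledge-purification hyperparameters.

    ``retain_fraction`` is the k-fraction of the retain set the student
    sees; the forget-weight schedule (``beta_init``, ``beta_multiplier``,
    ``beta_cap``) implements the audit feedback loop.
    """

    kd_weight: float = 0.5
    temperature: float = 2.0
    beta_init: float = 1.0
    beta_multiplier: float = 2.0
    beta_cap: float = 64.0
    target_p: float = 0.05
    patience: int = 3
    accuracy_budget: float = 0.05
    retain_fraction: float = 0.5
    alpha: float = 0.05
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        if not 0.0 <= self.kd_weight <= 1.0:
            raise ValueError("kd_weight must be in [0, 1]")
        if self.temperature <= 0 or self.beta_init < 0:
            raise ValueError("temperature must be > 0 and beta_init >= 0")
        if not 0.0 < self.retain_fraction <= 1.0:
            raise ValueError("retain_fraction must be in (0, 1]")


@dataclass
class TrainingTrace:
    """One record per completed epoch plus the stop reason."""

    hard_loss: list = field(default_factory=list)
    kd_loss: list = field(default_factory=list)
    forget_loss: list = field(default_factory=list)
    beta: list = field(default_factory=list)
    p_value: list = field(default_factory=list)
    test_accuracy: list = field(default_factory=list)
    stop_reason: str = "completed"

    def __len__(self) -> int:
        return len(self.p_value)


def afs_train(
    teacher,
    student_spec: ModelSpec,
    train: LabeledDataset,
    forget: QueryDataset,
    calibration: LabeledDataset,
    config: ForgetConfig | None = None,
    test: LabeledDataset | None = None,
    seed: int = 0,
    thresholds: ThresholdSet | None = None,
):
    """Train a student that forgets ``forget`` under audit feedback.

    Returns ``(student, trace)``.  With an empty forget set and
    ``beta_init = 0`` this reduces exactly to knowledge distillation on
    the k-fraction retain set (identical update sequence for the same
    seed).
    """
    config = config or ForgetConfig()
    fdata = forget.data if isinstance(forget, QueryDataset) else forget
    if teacher.num_classes != student_spec.num_classes:
        raise ValueError("teacher/student class-count mismatch")
    retain = retain_set(train, forget) if len(fdata) else train

    rng = np.random.default_rng(seed)
    n_keep = max(1, int(np.floor(config.retain_fraction * len(retain) + 0.5)))
    if n_keep < len(retain):
        retain_k = retain.take(rng.choice(len(retain), n_keep, replace=False))
    else:
        retain_k = retain

    if thresholds is None:
        thresholds = calibrate(student_spec, calibration, config.train, seed)

    student = build_model(student_spec, seed)
    opt = Adam(student.parameters, config.train)
    T, a_kd = config.temperature, config.kd_weight
    C = student.num_classes
    onehot = np.eye(C, dtype=np.float64)[retain_k.labels]
    # the teacher is frozen: its soft targets can be computed once
    teacher_soft = soften(teacher.predict_proba(retain_k.features), T)

    teacher_test_acc = evaluate_accuracy(teacher, test) if test is not None else None
    X, Xf = retain_k.features, fdata.features
    bs = config.train.batch_size
    beta = config.beta_init
    trace = TrainingTrace()
    below = 0
    fpos = 0  # cursor cycling through forget batches

    for epoch in range(config.train.epochs):
        order = rng.permutation(len(retain_k))
        eh = ek = ef = 0.0
        nb = 0
        for s in range(0, len(retain_k), bs):
            idx = order[s : s + bs]
            B = len(idx)
            p = softmax(student.forward_logits(X[idx])).astype(np.float64)
            p_soft = soften(p, T)
            tgt = teacher_soft[idx]
            dz = ((1.0 - a_kd) * (p - onehot[idx]) + a_kd * T * (p_soft - tgt)) / B
            student.backward(dz)
            eh += float(-(onehot[idx] * np.log(np.maximum(p, 1e-300))).sum(1).mean())
            ek += kd_loss(p_soft, tgt, T)
            nb += 1
            if beta > 0.0 and len(fdata):
                grads = [g.copy() for g in student.gradients]
                fidx = np.arange(fpos, fpos + min(bs, len(fdata))) % len(fdata)
                fpos = (fpos + len(fidx)) % len(fdata)
                pf = softmax(student.forward_logits(Xf[fidx])).astype(np.float64)
                nzf = pf > 0
                logp = np.log(np.where(nzf, pf, 1.0))
                ent = -(pf * logp).sum(1, keepdims=True)
                dzf = pf * (logp + ent) / len(fidx)  # grad of (ln C - mean entropy)
                student.backward(dzf)
                for g, gf in zip(grads, student.gradients):
                    gf *= beta
                    gf += g
                ef += forget_loss(pf)
            opt.step(student.gradients)

        trace.hard_loss.append(eh / nb)
        trace.kd_loss.append(ek / nb)
        trace.forget_loss.append(ef / nb)
        trace.beta.append(beta)

        if len(fdata):
            p_qf = audit_metric_matrix(
                metric_matrix(student, fdata), thresholds, config.alpha
            ).p_value
        else:
            p_qf = float("nan")
        trace.p_value.append(p_qf)
        acc = evaluate_accuracy(student, test) if test is not None else None
        trace.test_accuracy.append(acc)

        # negative feedback on the forget weight
        if len(fdata):
            if p_qf > config.target_p:
                beta = min(beta * config.beta_multiplier, config.beta_cap)
                below = 0
            else:
                beta = max(beta / config.beta_multiplier, config.beta_init)
                below += 1
            acc_ok = (
                teacher_test_acc is None
                or acc is None
                or acc >= teacher_test_acc - config.accuracy_budget
            )
            if below >= config.patience and acc_ok:
                trace.stop_reason = (
                    f"audit p <= {config.target_p} for {config.patience} epochs "
                    f"at epoch {epoch + 1}"
                )
                break

    return student, trace
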