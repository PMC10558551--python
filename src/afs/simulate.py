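"""Seeded synthetic classification data for audit/forget experiments.

Three generators cover the data shapes the tool handles: Gaussian-blob
tabular data, procedurally generated class-structured images, and an
EHR-style mixed binary/numeric table with a logistic label model.  All
are pure functions of their parameters and seed.

The module also pins the *reference blob study*: the fixed conditions
(pool size, dimensionality, class separation, split sizes, teacher and
student architectures, training protocol) under which every audit and
forgetting experiment in this package is run.  The blob geometry is
high-dimensional on purpose: with 500 features and unit isotropic noise
the reference training protocol (50 epochs, Adam, learning rate 1e-5,
batches of 8) drives the teacher to memorise its 1000 training points
nearly perfectly while held-out accuracy stays near chance — a strong,
reproducible overfit gap, which is precisely the signal membership
auditing exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LabeledDataset, SplitCollection, make_splits
from .models import ModelSpec
from .training import TrainConfig

__all__ = [
    "gen_gaussian_blobs",
    "gen_toy_images",
    "gen_ehr_table",
    "BlobStudy",
    "blob_study",
]


def _balanced_labels(n: int, C: int) -> np.ndarray:
    per = n // C
    counts = [per + (1 if c < n - per * C else 0) for c in range(C)]
    return np.concatenate([np.full(m, c, dtype=np.int64) for c, m in enumerate(counts)])


def gen_gaussian_blobs(
    n: int, C: int, d: int, separation: float, seed: int
) -> LabeledDataset:
    """Balanced C-class blobs: class ``c`` is centred at
    ``separation * e_{c mod d}`` with unit isotropic Gaussian noise."""
    if n < C:
        raise ValueError(f"need at least C={C} samples, got n={n}")
    if d < 1:
        raise ValueError("d must be >= 1")
    rng = np.random.default_rng(seed)
    labels = _balanced_labels(n, C)
    X = rng.normal(size=(n, d))
    X[np.arange(n), labels % d] += separation
    perm = rng.permutation(n)
    ids = np.array([f"b{seed}-{i}" for i in range(n)])
    return LabeledDataset(ids, X[perm], labels[perm], C)


def gen_toy_images(
    n: int, C: int, side: int = 16, noise: float = 0.1, seed: int = 0
) -> LabeledDataset:
    """Class-structured single-channel images: an oriented bar through the
    centre at a class-specific angle, plus pixel noise, clipped to [0, 1]."""
    if side < 8:
        raise ValueError("side must be >= 8")
    rng = np.random.default_rng(seed)
    labels = _balanced_labels(n, C)
    yy, xx = np.mgrid[0:side, 0:side] - (side - 1) / 2.0
    patterns = np.empty((C, side, side))
    for c in range(C):
        theta = np.pi * c / C
        dist = np.abs(xx * np.sin(theta) - yy * np.cos(theta))
        patterns[c] = (dist < side / 8.0).astype(np.float64)
    X = patterns[labels][:, None] + noise * rng.normal(size=(n, 1, side, side))
    X = np.clip(X, 0.0, 1.0)
    perm = rng.permutation(n)
    ids = np.array([f"img{seed}-{i}" for i in range(n)])
    return LabeledDataset(ids, X[perm], labels[perm], C)


def gen_ehr_table(n: int, p_features: int = 20, effect: float = 2.0, seed: int = 0) -> LabeledDataset:
    """EHR-like table: half Bernoulli, half numeric features; a binary
    label from a logistic model whose log-odds scale with ``effect``."""
    if p_features < 2:
        raise ValueError("p_features must be >= 2")
    rng = np.random.default_rng(seed)
    p_bin = p_features // 2
    Xb = rng.binomial(1, 0.3, size=(n, p_bin)).astype(np.float64)
    Xn = rng.normal(size=(n, p_features - p_bin))
    X = np.hstack([Xb, Xn])
    w = rng.choice([-1.0, 1.0], size=p_features) * rng.uniform(0.5, 1.5, p_features)
    logits = effect * (X - X.mean(axis=0)) @ w / np.sqrt(p_features)
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-logits))).astype(np.int64)
    ids = np.array([f"ehr{seed}-{i}" for i in range(n)])
    return LabeledDataset(ids, X, y, 2)


# ---------------------------------------------------------------------------
# Reference study conditions

@dataclass(frozen=True)
class BlobStudy:
    """The fixed experimental conditions for blob-fixture studies."""

    splits: SplitCollection
    teacher_spec: ModelSpec
    student_spec: ModelSpec
    train_config: TrainConfig
    seed: int


def blob_study(
    seed: int,
    n_pool: int = 5000,
    C: int = 5,
    d: int = 500,
    separation: float = 3.0,
    train_n: int = 1000,
    test_n: int = 500,
    cal_n: int = 1000,
) -> BlobStudy:
    """Build the reference blob study for one replicate seed.

    Defaults: a 5000-sample pool of 5 classes in 500 dimensions at
    separation 3, split 1000/500/1000 into train/test/calibration with
    the rest held out for non-member queries; a 512x256 MLP teacher, a
    256x128 MLP student, and the reference training protocol (50 epochs,
    Adam, lr 1e-5, batch 8).
    """
    pool = gen_gaussian_blobs(n_pool, C, d, separation, seed)
    splits = make_splits(pool, train_n, test_n, cal_n, seed)
    teacher = ModelSpec("mlp", C, (d,), hidden=(512, 256))
    student = ModelSpec("mlp", C, (d,), hidden=(256, 128))
    return BlobStudy(splits, teacher, student, TrainConfig(), seed)
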