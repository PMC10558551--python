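"""Labeled datasets, train/test/calibration splits and query-set construction.

The unit of bookkeeping is the :class:`LabeledDataset`: features, integer
class labels and *stable sample ids*.  All membership questions ("was this
sample used for training?") are decided by id, never by feature equality,
so splits and query sets remain well-defined after serialisation.

Query datasets come in four flavours used throughout the auditing and
forgetting experiments:

* ``QO``  — fully overlapping the training set (purity ``k = 1``),
* ``QNO`` — fully disjoint from it (``k = 0``),
* ``QM``  — mixed, with a requested fraction ``k`` of members,
* ``QF``  — a subset of the training set designated to be forgotten.

Purity is ``k = |query ids ∩ train ids| / |query|``.  Mixed queries draw
their non-member part from a dedicated held-out pool that is never used
for training, testing or calibration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "SplitCollection",
    "QueryMode",
    "QueryDataset",
    "make_splits",
    "build_query",
    "overlap_fraction",
    "retain_set",
    "load_csv",
    "save_csv",
    "load_npz",
    "save_npz",
    "load_image_dir",
    "save_image_dir",
]


@dataclass(frozen=True)
class LabeledDataset:
    """Features + integer class labels + unique sample ids.

    ``features`` is ``(n, d)`` for tabular data or ``(n, C, H, W)`` for
    images; ``labels`` are class indices in ``0..num_classes-1``.
    ``num_classes`` is declared, not inferred, so a split may lack some
    classes without changing the label space.
    """

    ids: np.ndarray
    features: np.ndarray
    labels: np.ndarray
    num_classes: int

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids)
        features = np.asarray(self.features)
        labels = np.asarray(self.labels, dtype=np.int64)
        if not (len(ids) == len(features) == len(labels)):
            raise ValueError(
                f"length mismatch: {len(ids)} ids, {len(features)} feature "
                f"rows, {len(labels)} labels"
            )
        if len(np.unique(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        if self.num_classes < 1:
            raise ValueError("num_classes must be positive")
        if len(labels) and (labels.min() < 0 or labels.max() >= self.num_classes):
            raise ValueError(
                f"labels must lie in 0..{self.num_classes - 1}; "
                f"found range [{labels.min()}, {labels.max()}]"
            )
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "features", features)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def id_set(self) -> frozenset:
        return frozenset(self.ids.tolist())

    def take(self, indices: np.ndarray) -> "LabeledDataset":
        """Positional subset (preserves order of ``indices``)."""
        indices = np.asarray(indices)
        return LabeledDataset(
            self.ids[indices],
            self.features[indices],
            self.labels[indices],
            self.num_classes,
        )

    def select_ids(self, ids) -> "LabeledDataset":
        """Subset by sample id, in the order given."""
        pos = {s: i for i, s in enumerate(self.ids.tolist())}
        try:
            idx = np.array([pos[s] for s in ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"sample id {exc.args[0]!r} not in dataset") from exc
        return self.take(idx)


@dataclass(frozen=True)
class SplitCollection:
    """Pairwise id-disjoint train/test/calibration splits plus a held-out
    pool from which non-member query samples are drawn."""

    train: LabeledDataset
    test: LabeledDataset
    calibration: LabeledDataset
    heldout: LabeledDataset
    seed: int

    def __post_init__(self) -> None:
        parts = {
            "train": self.train.id_set,
            "test": self.test.id_set,
            "calibration": self.calibration.id_set,
            "heldout": self.heldout.id_set,
        }
        names = list(parts)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                inter = parts[a] & parts[b]
                if inter:
                    raise ValueError(
                        f"splits {a} and {b} share {len(inter)} sample ids"
                    )


class QueryMode(str, Enum):
    QO = "QO"    # fully overlapping the training set
    QNO = "QNO"  # fully disjoint from the training set
    QM = "QM"    # mixed with purity k
    QF = "QF"    # training subset designated for forgetting


@dataclass(frozen=True)
class QueryDataset:
    """A query dataset plus its membership bookkeeping."""

    data: LabeledDataset
    mode: QueryMode
    overlap_fraction: float
    member_ids: frozenset = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.data)


def make_splits(
    pool: LabeledDataset,
    train_n: int,
    test_n: int,
    cal_n: int,
    seed: int,
) -> SplitCollection:
    """Randomly partition ``pool`` into disjoint train/test/calibration
    splits; whatever remains becomes the held-out non-member pool.

    Sampling is without replacement and fully determined by ``seed``.
    """
    need = train_n + test_n + cal_n
    if need > len(pool):
        raise ValueError(
            f"requested {need} samples (train {train_n} + test {test_n} + "
            f"calibration {cal_n}) but the pool holds only {len(pool)}; "
            f"short by {need - len(pool)}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pool))
    tr = pool.take(perm[:train_n])
    te = pool.take(perm[train_n : train_n + test_n])
    ca = pool.take(perm[train_n + test_n : need])
    ho = pool.take(perm[need:])
    return SplitCollection(tr, te, ca, ho, seed)


def build_query(
    splits: SplitCollection,
    mode: QueryMode | str,
    size: int,
    k: float = 0.0,
    seed: int = 0,
) -> QueryDataset:
    """Draw a query dataset of ``size`` samples of the requested mode.

    ``QM`` mixes ``round(k * size)`` training members (rounding half away
    from zero) with non-members from the held-out pool; the *realised*
    purity ``round(k*size)/size`` is stored.  ``QO``/``QF`` draw from the
    training set, ``QNO`` from the held-out pool.
    """
    mode = QueryMode(mode)
    if size < 1:
        raise ValueError("query size must be >= 1")
    if not 0.0 <= k <= 1.0:
        raise ValueError(f"purity k must be in [0, 1], got {k}")
    rng = np.random.default_rng(seed)
    train, heldout = splits.train, splits.heldout

    if mode in (QueryMode.QO, QueryMode.QF):
        n_member, n_non = size, 0
    elif mode is QueryMode.QNO:
        n_member, n_non = 0, size
    else:  # QM: round half away from zero
        n_member = int(np.floor(k * size + 0.5))
        n_non = size - n_member

    if n_member > len(train):
        raise ValueError(
            f"{mode.value} query needs {n_member} training members but the "
            f"training set holds {len(train)}"
        )
    if n_non > len(heldout):
        raise ValueError(
            f"{mode.value} query needs {n_non} non-members but the held-out "
            f"pool holds {len(heldout)}"
        )

    parts = []
    if n_member:
        parts.append(train.take(rng.choice(len(train), n_member, replace=False)))
    if n_non:
        parts.append(heldout.take(rng.choice(len(heldout), n_non, replace=False)))
    if len(parts) == 1:
        data = parts[0]
    else:
        data = LabeledDataset(
            np.concatenate([p.ids for p in parts]),
            np.concatenate([p.features for p in parts]),
            np.concatenate([p.labels for p in parts]),
            train.num_classes,
        )
        # shuffle so members and non-members are interleaved
        data = data.take(rng.permutation(len(data)))

    realized_k = n_member / size
    member_ids = frozenset(np.asarray(parts[0].ids).tolist()) if n_member else frozenset()
    return QueryDataset(data, mode, realized_k, member_ids)


def overlap_fraction(query: QueryDataset | LabeledDataset, train: LabeledDataset) -> float:
    """Fraction of query sample ids present in the training set."""
    data = query.data if isinstance(query, QueryDataset) else query
    if len(data) == 0:
        raise ValueError("cannot compute overlap of an empty query")
    return len(data.id_set & train.id_set) / len(data)


def retain_set(train: LabeledDataset, forget: QueryDataset | LabeledDataset) -> LabeledDataset:
    """Training set minus the forget set (the retain set D_r)."""
    fdata = forget.data if isinstance(forget, QueryDataset) else forget
    fids = fdata.id_set
    missing = fids - train.id_set
    if missing:
        raise ValueError(
            f"{len(missing)} forget ids are not in the training set "
            f"(e.g. {sorted(missing)[:3]})"
        )
    keep = np.array([s not in fids for s in train.ids.tolist()])
    if not keep.any():
        warnings.warn("forget set covers the entire training set; retain set is empty")
    return train.take(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Serialisation: CSV tables, npz containers, directory-per-class PNG trees.

def save_csv(data: LabeledDataset, path) -> None:
    if data.features.ndim != 2:
        raise ValueError("CSV serialisation supports tabular (n, d) features only")
    df = pd.DataFrame(data.features, columns=[f"x{i}" for i in range(data.features.shape[1])])
    df.insert(0, "id", data.ids)
    df["label"] = data.labels
    df.to_csv(path, index=False)


def load_csv(path, num_classes: int | None = None, label_column: str = "label") -> LabeledDataset:
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ValueError(f"no {label_column!r} column in {path}")
    labels = df[label_column].to_numpy(dtype=np.int64)
    ids = df["id"].to_numpy() if "id" in df.columns else np.arange(len(df))
    feats = df.drop(columns=[c for c in ("id", label_column) if c in df.columns])
    C = num_classes if num_classes is not None else int(labels.max()) + 1
    return LabeledDataset(ids, feats.to_numpy(dtype=np.float64), labels, C)


def save_npz(data: LabeledDataset, path) -> None:
    np.savez(
        path,
        ids=data.ids,
        features=data.features,
        labels=data.labels,
        num_classes=np.int64(data.num_classes),
    )


def load_npz(path) -> LabeledDataset:
    with np.load(path, allow_pickle=False) as f:
        return LabeledDataset(f["ids"], f["features"], f["labels"], int(f["num_classes"]))


def save_image_dir(data: LabeledDataset, root) -> None:
    """Write single-channel images as ``root/<class>/<id>.png``."""
    from PIL import Image

    root = Path(root)
    if data.features.ndim != 4 or data.features.shape[1] != 1:
        raise ValueError("image serialisation expects (n, 1, H, W) features")
    for sid, img, lab in zip(data.ids, data.features, data.labels):
        d = root / str(int(lab))
        d.mkdir(parents=True, exist_ok=True)
        arr = np.clip(np.rint(img[0] * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(d / f"{sid}.png")


def load_image_dir(root, num_classes: int | None = None) -> LabeledDataset:
    """Read a directory-per-class PNG tree written by :func:`save_image_dir`."""
    from PIL import Image

    root = Path(root)
    ids, feats, labels = [], [], []
    classes = sorted((p for p in root.iterdir() if p.is_dir()), key=lambda p: int(p.name))
    for cdir in classes:
        for png in sorted(cdir.glob("*.png")):
            ids.append(png.stem)
            feats.append(np.asarray(Image.open(png), dtype=np.float64)[None] / 255.0)
            labels.append(int(cdir.name))
    C = num_classes if num_classes is not None else (max(labels) + 1 if labels else 1)
    return LabeledDataset(np.array(ids), np.stack(feats), np.array(labels), C)


def save_ids(data: LabeledDataset, path) -> None:
    """Persist the id list as a JSON array so splits are replayable."""
    Path(path).write_text(json.dumps(np.asarray(data.ids).tolist()))


def load_ids(path) -> list:
    return json.loads(Path(path).read_text())
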