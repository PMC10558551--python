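"""Unlearning baselines: independent retraining, SISA, CF-k and EU-k.

* ``train_independent`` — retrain from scratch on a k-fraction of the
  training data with the forget set excluded (the "Independent
  teacher/student" comparison points).
* SISA — shard the training data, train one model per shard, predict by
  majority vote; unlearning retrains only the shards containing the
  forget samples.
* CF-k — fine-tune the last k parameter groups of the original model on
  the retain set, freezing the rest.
* EU-k — like CF-k but the last k groups are re-initialised from
  scratch before retraining.

CF-k/EU-k exploit that the frozen prefix is constant: its activations
are computed once and the trainable suffix is trained on those cached
features, which is mathematically identical to masked full training.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass

import numpy as np

from .data import LabeledDataset, QueryDataset
from .models import Dense, ModelSpec, build_model, fingerprint_params
from .training import TrainConfig, train_supervised

__all__ = [
    "train_independent",
    "ShardedModel",
    "sisa_train",
    "sisa_unlearn",
    "sisa_predict",
    "cf_k",
    "eu_k",
]


def train_independent(
    spec: ModelSpec,
    train: LabeledDataset,
    k: float = 1.0,
    exclude: QueryDataset | LabeledDataset | None = None,
    seed: int = 0,
    config: TrainConfig | None = None,
):
    """Retrain ``spec`` from scratch on a seeded k-fraction of
    ``train`` minus ``exclude``."""
    if not 0.0 < k <= 1.0:
        raise ValueError("k must be in (0, 1]")
    data = train
    if exclude is not None:
        edata = exclude.data if isinstance(exclude, QueryDataset) else exclude
        eids = edata.id_set & train.id_set
        if eids:
            keep = np.array([s not in eids for s in train.ids.tolist()])
            data = train.take(np.flatnonzero(keep))
    n_keep = int(np.floor(k * len(data) + 0.5))
    if n_keep < 1:
        raise ValueError("k-fraction of the training data is empty")
    if n_keep < len(data):
        rng = np.random.default_rng(seed)
        data = data.take(rng.choice(len(data), n_keep, replace=False))
    model = build_model(spec, seed)
    return train_supervised(model, data, config or TrainConfig(), seed)


# ---------------------------------------------------------------------------
# SISA

def _shard_of(sample_id, n_shards: int, seed: int) -> int:
    h = hashlib.sha256(f"{seed}:{sample_id}".encode()).digest()
    return int.from_bytes(h[:8], "big") % n_shards


@dataclass
class ShardedModel:
    """Per-shard models over a seeded id-hash partition of the data."""

    spec: ModelSpec
    assignment: dict           # sample id -> shard index
    models: list
    train_data: LabeledDataset
    n_shards: int
    seed: int
    config: TrainConfig

    @property
    def num_classes(self) -> int:
        return self.spec.num_classes

    def shard_members(self, shard: int) -> LabeledDataset:
        keep = [i for i, s in enumerate(self.train_data.ids.tolist())
                if self.assignment.get(s) == shard]
        return self.train_data.take(np.array(keep, dtype=np.int64))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return sisa_predict(self, X)

    @property
    def parameter_count(self) -> int:
        return int(sum(m.parameter_count for m in self.models))

    @property
    def fingerprint(self) -> str:
        return fingerprint_params(
            [p for m in self.models for p in m.parameters]
        )


def sisa_train(
    spec: ModelSpec,
    train: LabeledDataset,
    n_shards: int = 10,
    seed: int = 0,
    config: TrainConfig | None = None,
) -> ShardedModel:
    """Shard ``train`` by seeded id hashing and train one model per shard."""
    config = config or TrainConfig()
    assignment = {s: _shard_of(s, n_shards, seed) for s in train.ids.tolist()}
    models = []
    for shard in range(n_shards):
        keep = [i for i, s in enumerate(train.ids.tolist()) if assignment[s] == shard]
        sub = train.take(np.array(keep, dtype=np.int64))
        model = build_model(spec, seed * n_shards + shard)
        if len(sub):
            train_supervised(model, sub, config, seed * n_shards + shard)
        models.append(model)
    return ShardedModel(spec, assignment, models, train, n_shards, seed, config)


def sisa_unlearn(model: ShardedModel, forget: QueryDataset | LabeledDataset) -> ShardedModel:
    """Retrain only the shards containing forget samples (on the shard
    minus those samples); untouched shard models are reused as-is."""
    fdata = forget.data if isinstance(forget, QueryDataset) else forget
    fids = fdata.id_set
    unmapped = fids - set(model.assignment)
    if unmapped:
        raise ValueError(f"{len(unmapped)} forget ids are not in the sharded training data")
    affected = sorted({model.assignment[s] for s in fids})

    keep_rows = np.array([s not in fids for s in model.train_data.ids.tolist()])
    new_train = model.train_data.take(np.flatnonzero(keep_rows))
    new_models = list(model.models)
    for shard in affected:
        keep = [i for i, s in enumerate(new_train.ids.tolist())
                if model.assignment[s] == shard]
        sub = new_train.take(np.array(keep, dtype=np.int64))
        m = build_model(model.spec, model.seed * model.n_shards + shard)
        if len(sub):
            train_supervised(m, sub, model.config, model.seed * model.n_shards + shard)
        new_models[shard] = m
    assignment = {s: sh for s, sh in model.assignment.items() if s not in fids}
    return ShardedModel(model.spec, assignment, new_models, new_train,
                        model.n_shards, model.seed, model.config)


def sisa_predict(model: ShardedModel, X: np.ndarray) -> np.ndarray:
    """Majority vote over shard arg-maxes; output rows are vote shares
    (ties resolve to the lowest class index via arg-max of counts)."""
    C = model.num_classes
    votes = np.zeros((len(X), C))
    for m in model.models:
        pred = m.predict_proba(X).argmax(axis=1)
        votes[np.arange(len(X)), pred] += 1.0
    return votes / votes.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# CF-k / EU-k

def _split_at_group(model, k_layers: int):
    """Split layer list so the last ``k_layers`` parameter groups are
    trainable; returns (prefix_layers, suffix_layers)."""
    groups = model.parameter_groups()
    depth = len(groups)
    if not 1 <= k_layers <= depth:
        raise ValueError(f"k_layers must be in 1..{depth}, got {k_layers}")
    first_trainable = groups[depth - k_layers][0]
    idx = int(first_trainable.split(":")[0])
    return model.layers[:idx], model.layers[idx:]


def _make_suffix(model, layers):
    sub = copy.copy(model)
    sub.layers = layers
    return sub


def _prefix_features(layers, X, dtype, batch_size=512):
    out = []
    for s in range(0, len(X), batch_size):
        h = np.asarray(X[s : s + batch_size], dtype=dtype)
        if h.ndim > 2:
            h = h.reshape(len(h), -1)
        for layer in layers:
            h = layer.forward(h)
        out.append(h)
    return np.vstack(out)


def _train_tail(model, retain, k_layers, seed, config, reinit):
    config = config or TrainConfig()
    new = copy.deepcopy(model)
    prefix, suffix = _split_at_group(new, k_layers)
    if reinit:
        rng = np.random.default_rng(seed)
        for layer in suffix:
            if isinstance(layer, Dense):
                nin, nout = layer.W.shape
                fresh = Dense(nin, nout, rng, layer.W.dtype)
                layer.W[...] = fresh.W
                layer.b[...] = fresh.b
    if len(retain) == 0:
        raise ValueError("retain set is empty")
    feats = _prefix_features(prefix, retain.features, new.dtype)
    tail = _make_suffix(new, suffix)
    train_supervised(tail, LabeledDataset(retain.ids, feats, retain.labels,
                                          retain.num_classes), config, seed)
    new.layers = prefix + tail.layers
    return new


def cf_k(model, retain: LabeledDataset, k_layers: int,
         config: TrainConfig | None = None, seed: int = 0):
    """Catastrophic-forgetting unlearning: fine-tune the last ``k_layers``
    parameter groups on the retain set from their current values."""
    return _train_tail(model, retain, k_layers, seed, config, reinit=False)


def eu_k(model, retain: LabeledDataset, k_layers: int, seed: int = 0,
         config: TrainConfig | None = None):
    """Exact-unlearning-k: re-initialise the last ``k_layers`` parameter
    groups from ``seed`` and retrain them on the retain set."""
    return _train_tail(model, retain, k_layers, seed, config, reinit=True)
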