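"""Supervised training for the registry networks.

The reference protocol used by all audit/forget experiments is the one
the experiments are calibrated to: 50 epochs, Adam with learning rate
1e-5, minibatches of 8.  ``TrainConfig`` makes each of these a knob.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LabeledDataset
from .models import softmax

__all__ = ["TrainConfig", "Adam", "train_supervised", "evaluate_accuracy"]


@dataclass
class TrainConfig:
    epochs: int = 50
    lr: float = 1e-5
    batch_size: int = 8
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.lr <= 0 or self.batch_size < 1:
            raise ValueError("lr must be > 0 and batch_size >= 1")


class Adam:
    """Adaptive-moment optimiser over a fixed list of parameter arrays."""

    def __init__(self, params, config: TrainConfig):
        self.params = list(params)
        self.cfg = config
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1 ** self.t
        bc2 = 1.0 - c.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= c.beta1
            m += (1 - c.beta1) * g
            v *= c.beta2
            v += (1 - c.beta2) * g * g
            p -= c.lr * (m / bc1) / (np.sqrt(v / bc2) + c.eps)


def train_supervised(model, data: LabeledDataset, config: TrainConfig, seed: int):
    """Train ``model`` in place on hard labels (cross-entropy); returns it.

    Deterministic for a fixed (model init, data, config, seed).  With
    ``epochs=0`` the model is returned untouched.
    """
    if len(data) == 0:
        raise ValueError("cannot train on an empty dataset")
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters, config)
    onehot = np.eye(model.num_classes, dtype=np.float32)[data.labels]
    X = data.features
    for _ in range(config.epochs):
        order = rng.permutation(len(data))
        for s in range(0, len(data), config.batch_size):
            idx = order[s : s + config.batch_size]
            p = softmax(model.forward_logits(X[idx]))
            model.backward((p - onehot[idx]) / len(idx))
            opt.step(model.gradients)
    return model


def evaluate_accuracy(model, data: LabeledDataset, batch_size: int = 256) -> float:
    if len(data) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    correct = 0
    for s in range(0, len(data), batch_size):
        p = model.predict_proba(data.features[s : s + batch_size])
        correct += int((p.argmax(axis=1) == data.labels[s : s + batch_size]).sum())
    return correct / len(data)
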