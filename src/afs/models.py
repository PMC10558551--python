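"""Model registry: numpy classifiers with a shared probabilistic contract.

Every model exposes ``predict_proba`` (rows on the probability simplex),
``num_classes``, ``parameter_count`` (trainable parameters only) and
``fingerprint`` (a stable content hash of the parameters, used for
freezing/identity contracts in the unlearning baselines).

Four families are registered:

* ``mlp``       — fully connected ReLU network; training supported.
* ``small_cnn`` — two 3x3 conv blocks + global average pooling; training
  supported (im2col convolutions).
* ``resnet18`` / ``resnet34`` — the standard residual-network layer plan
  (7x7 stem, four stages of basic blocks, batch-norm affine parameters,
  final fully connected head).  These entries provide seeded parameter
  instantiation, exact parameter accounting and forward inference; they
  are reference architectures, not training targets, in this package.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

__all__ = [
    "ProbabilisticClassifier",
    "ModelSpec",
    "build_model",
    "save_model",
    "load_model",
    "MLPNet",
    "SmallCNN",
    "ResNet",
    "softmax",
    "fingerprint_params",
]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def fingerprint_params(params: Sequence[np.ndarray]) -> str:
    h = hashlib.sha256()
    for p in params:
        h.update(str(p.shape).encode())
        h.update(np.ascontiguousarray(p, dtype=np.float32).tobytes())
    return h.hexdigest()


@runtime_checkable
class ProbabilisticClassifier(Protocol):
    num_classes: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray: ...

    @property
    def parameter_count(self) -> int: ...

    @property
    def fingerprint(self) -> str: ...


# ---------------------------------------------------------------------------
# Layers

class Dense:
    def __init__(self, nin: int, nout: int, rng: np.random.Generator, dtype=np.float32):
        self.W = rng.normal(0.0, np.sqrt(2.0 / nin), (nin, nout)).astype(dtype)
        self.b = np.zeros(nout, dtype=dtype)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, d):
        self.gW = self._x.T @ d
        self.gb = d.sum(axis=0)
        return d @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.gW, self.gb]


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, d):
        return d * self._mask


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> (N, Hout*Wout, C*kh*kw) patch matrix."""
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Hout, Wout, kh, kw)
    n, c, ho, wo, _, _ = win.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw), ho, wo


class Conv2d:
    def __init__(self, cin, cout, k, rng, stride=1, pad=0, bias=True, dtype=np.float32):
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, k, k)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype) if bias else None
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x):
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2))
        self._xp_shape = x.shape
        col, ho, wo = _im2col(x, self.k, self.k, self.stride)
        self._col, self._ho, self._wo = col, ho, wo
        cout = self.W.shape[0]
        out = col @ self.W.reshape(cout, -1).T  # (N, Ho*Wo, Cout)
        if self.b is not None:
            out = out + self.b
        return out.transpose(0, 2, 1).reshape(x.shape[0], cout, ho, wo)

    def backward(self, d):
        n, cout, ho, wo = d.shape
        dmat = d.reshape(n, cout, ho * wo).transpose(0, 2, 1)  # (N, P, Cout)
        self.gW = np.einsum("npc,npk->ck", dmat, self._col).reshape(self.W.shape)
        if self.b is not None:
            self.gb = dmat.sum(axis=(0, 1))
        dcol = dmat @ self.W.reshape(cout, -1)  # (N, P, C*k*k)
        # scatter patches back (col2im)
        N, C, H, W = self._xp_shape
        dx = np.zeros(self._xp_shape, dtype=d.dtype)
        dcol = dcol.reshape(n, ho, wo, C, self.k, self.k)
        for i in range(self.k):
            for j in range(self.k):
                dx[:, :, i : i + ho * self.stride : self.stride,
                   j : j + wo * self.stride : self.stride] += dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if self.pad:
            dx = dx[:, :, self.pad : H - self.pad, self.pad : W - self.pad]
        return dx

    @property
    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    @property
    def grads(self):
        return [self.gW] + ([self.gb] if self.b is not None else [])


class AvgPool2d:
    """Non-overlapping average pooling (kernel == stride)."""

    params: list = []
    grads: list = []

    def __init__(self, k: int):
        self.k = k

    def forward(self, x):
        n, c, h, w = x.shape
        k = self.k
        self._shape = x.shape
        return x[:, :, : h - h % k, : w - w % k].reshape(
            n, c, h // k, k, w // k, k
        ).mean(axis=(3, 5))

    def backward(self, d):
        n, c, h, w = self._shape
        k = self.k
        dx = np.zeros(self._shape, dtype=d.dtype)
        up = np.repeat(np.repeat(d, k, axis=2), k, axis=3) / (k * k)
        dx[:, :, : up.shape[2], : up.shape[3]] = up
        return dx


class GlobalAvgPool:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, d):
        n, c, h, w = self._shape
        return np.broadcast_to(d[:, :, None, None] / (h * w), self._shape).copy()


class BatchNorm2d:
    """Batch normalisation with affine parameters; inference uses running
    statistics (initialised to mean 0, variance 1)."""

    def __init__(self, c: int, dtype=np.float32, eps: float = 1e-5):
        self.weight = np.ones(c, dtype=dtype)
        self.bias = np.zeros(c, dtype=dtype)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.eps = eps

    def forward(self, x):
        scale = self.weight / np.sqrt(self.running_var + self.eps)
        return x * scale[None, :, None, None] + (
            self.bias - self.running_mean * scale
        )[None, :, None, None]

    @property
    def params(self):
        return [self.weight, self.bias]


class MaxPool2d:
    params: list = []
    grads: list = []

    def __init__(self, k: int, stride: int, pad: int = 0):
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x):
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2),
                       constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        return win[:, :, ::self.stride, ::self.stride].max(axis=(4, 5))


# ---------------------------------------------------------------------------
# Trainable feed-forward networks

class _FeedForward:
    """Base for layer-list networks with manual backprop."""

    layers: list
    num_classes: int

    def forward_logits(self, X: np.ndarray) -> np.ndarray:
        h = X.astype(self.dtype, copy=False)
        for layer in self.layers:
            h = layer.forward(h)
        return h

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.forward_logits(X))

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits.astype(self.dtype, copy=False)
        for layer in reversed(self.layers):
            d = layer.backward(d)

    @property
    def parameters(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self):
        return [g for layer in self.layers for g in layer.grads]

    def parameter_groups(self):
        """Named parameter groups in depth order (freezing granularity)."""
        out = []
        for i, layer in enumerate(self.layers):
            if layer.params:
                out.append((f"{i}:{type(layer).__name__}", layer.params))
        return out

    @property
    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.parameters))

    @property
    def fingerprint(self) -> str:
        return fingerprint_params(self.parameters)


class MLPNet(_FeedForward):
    def __init__(self, input_dim, hidden, num_classes, seed, dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.dtype = dtype
        self.num_classes = num_classes
        self.input_dim = input_dim
        dims = [int(np.prod(input_dim))] + list(hidden) + [num_classes]
        self.layers = []
        for i in range(len(dims) - 1):
            self.layers.append(Dense(dims[i], dims[i + 1], rng, dtype))
            if i < len(dims) - 2:
                self.layers.append(ReLU())

    def forward_logits(self, X):
        X = np.asarray(X)
        if X.ndim > 2:
            X = X.reshape(len(X), -1)
        return super().forward_logits(X)


class SmallCNN(_FeedForward):
    """conv3x3 -> ReLU -> avgpool2 -> conv3x3 -> ReLU -> GAP -> linear."""

    def __init__(self, in_shape, num_classes, seed, channels=(8, 16), dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.dtype = dtype
        self.num_classes = num_classes
        cin = in_shape[0]
        c1, c2 = channels
        self.layers = [
            Conv2d(cin, c1, 3, rng, pad=1, dtype=dtype),
            ReLU(),
            AvgPool2d(2),
            Conv2d(c1, c2, 3, rng, pad=1, dtype=dtype),
            ReLU(),
            GlobalAvgPool(),
            Dense(c2, num_classes, rng, dtype),
        ]


# ---------------------------------------------------------------------------
# Residual networks (reference layer plans; forward inference only)

class _BasicBlock:
    expansion = 1

    def __init__(self, cin, cout, stride, rng, dtype=np.float32):
        self.conv1 = Conv2d(cin, cout, 3, rng, stride=stride, pad=1, bias=False, dtype=dtype)
        self.bn1 = BatchNorm2d(cout, dtype)
        self.conv2 = Conv2d(cout, cout, 3, rng, stride=1, pad=1, bias=False, dtype=dtype)
        self.bn2 = BatchNorm2d(cout, dtype)
        self.relu = ReLU()
        if stride != 1 or cin != cout:
            self.down_conv = Conv2d(cin, cout, 1, rng, stride=stride, bias=False, dtype=dtype)
            self.down_bn = BatchNorm2d(cout, dtype)
        else:
            self.down_conv = self.down_bn = None

    def forward(self, x):
        out = self.bn1.forward(self.conv1.forward(x))
        out = np.maximum(out, 0)
        out = self.bn2.forward(self.conv2.forward(out))
        if self.down_conv is not None:
            x = self.down_bn.forward(self.down_conv.forward(x))
        return np.maximum(out + x, 0)

    @property
    def params(self):
        ps = self.conv1.params + self.bn1.params + self.conv2.params + self.bn2.params
        if self.down_conv is not None:
            ps += self.down_conv.params + self.down_bn.params
        return ps


class ResNet:
    """Standard residual network with basic blocks.

    ``depth=18`` uses stage sizes (2, 2, 2, 2), ``depth=34`` uses
    (3, 4, 6, 3); stage widths are 64/128/256/512.  Inputs are
    ``(N, in_channels, H, W)`` with H, W >= 32.
    """

    PLANS = {18: (2, 2, 2, 2), 34: (3, 4, 6, 3)}

    def __init__(self, depth, num_classes, seed, in_channels=3, dtype=np.float32):
        if depth not in self.PLANS:
            raise ValueError(f"unsupported residual depth {depth}; choose 18 or 34")
        rng = np.random.default_rng(seed)
        self.dtype = dtype
        self.num_classes = num_classes
        self.conv1 = Conv2d(in_channels, 64, 7, rng, stride=2, pad=3, bias=False, dtype=dtype)
        self.bn1 = BatchNorm2d(64, dtype)
        self.maxpool = MaxPool2d(3, 2, 1)
        self.blocks = []
        cin = 64
        for stage, nblocks in enumerate(self.PLANS[depth]):
            cout = 64 * (2 ** stage)
            for b in range(nblocks):
                stride = 2 if (stage > 0 and b == 0) else 1
                self.blocks.append(_BasicBlock(cin, cout, stride, rng, dtype))
                cin = cout
        self.fc = Dense(512, num_classes, rng, dtype)

    def forward_logits(self, X):
        h = self.maxpool.forward(np.maximum(self.bn1.forward(self.conv1.forward(
            np.asarray(X, dtype=self.dtype))), 0))
        for blk in self.blocks:
            h = blk.forward(h)
        h = h.mean(axis=(2, 3))
        return self.fc.forward(h)

    def predict_proba(self, X):
        return softmax(self.forward_logits(X))

    @property
    def parameters(self):
        ps = self.conv1.params + self.bn1.params
        for blk in self.blocks:
            ps += blk.params
        return ps + self.fc.params

    @property
    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.parameters))

    @property
    def fingerprint(self) -> str:
        return fingerprint_params(self.parameters)


# ---------------------------------------------------------------------------
# Registry

@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description resolvable by :func:`build_model`."""

    family: str
    num_classes: int
    input_shape: tuple = ()
    hidden: tuple = (256, 128)
    channels: tuple = (8, 16)

    def smaller(self) -> "ModelSpec":
        """A student-sized spec of the same family (roughly half widths)."""
        if self.family == "mlp":
            return ModelSpec("mlp", self.num_classes, self.input_shape,
                             tuple(max(h // 2, 4) for h in self.hidden), self.channels)
        if self.family == "small_cnn":
            return ModelSpec("small_cnn", self.num_classes, self.input_shape,
                             self.hidden, tuple(max(c // 2, 2) for c in self.channels))
        if self.family == "resnet34":
            return ModelSpec("resnet18", self.num_classes, self.input_shape)
        raise ValueError(f"no smaller counterpart registered for {self.family!r}")


def build_model(spec: ModelSpec, seed: int):
    """Instantiate a registry model with seeded initialisation."""
    if spec.family == "mlp":
        model = MLPNet(spec.input_shape, spec.hidden, spec.num_classes, seed)
    elif spec.family == "small_cnn":
        model = SmallCNN(spec.input_shape, spec.num_classes, seed, spec.channels)
    elif spec.family in ("resnet18", "resnet34"):
        depth = int(spec.family[-2:])
        cin = spec.input_shape[0] if spec.input_shape else 3
        model = ResNet(depth, spec.num_classes, seed, in_channels=cin)
    else:
        raise ValueError(f"unknown model family {spec.family!r}")
    model.spec = spec
    return model


def save_model(model, path) -> None:
    """Checkpoint a registry model (spec + parameters) as an npz file."""
    import json

    spec = getattr(model, "spec", None)
    if spec is None:
        raise ValueError("model carries no spec; only registry models are checkpointable")
    header = json.dumps({
        "family": spec.family,
        "num_classes": spec.num_classes,
        "input_shape": list(spec.input_shape),
        "hidden": list(spec.hidden),
        "channels": list(spec.channels),
    })
    arrays = {f"p{i}": p for i, p in enumerate(model.parameters)}
    np.savez(path, __spec__=np.array(header), **arrays)


def load_model(path):
    """Rebuild a checkpointed registry model."""
    import json

    with np.load(path, allow_pickle=False) as f:
        header = json.loads(str(f["__spec__"]))
        spec = ModelSpec(
            header["family"], header["num_classes"], tuple(header["input_shape"]),
            tuple(header["hidden"]), tuple(header["channels"]),
        )
        model = build_model(spec, seed=0)
        for i, p in enumerate(model.parameters):
            p[...] = f[f"p{i}"]
    return model
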