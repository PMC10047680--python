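"""Multichannel 3D CNN node-feature encoder.

Stacked summary volumes (one channel per derivative, 19 with the full
set) are classified by a 3D convolutional network and the penultimate
dense layer (default 1024 units, post-ReLU, dropout inactive) is
exposed as each subject's node-feature vector.

Architecture: a first convolution block (default 16 filters) followed
by four repeated blocks with 32, 64, 128 and 256 filters.  A block is
conv(3x3x3, same padding) -> ReLU -> batch norm -> max-pool(2x2x2,
valid).  Global average pooling feeds a dense ReLU layer, dropout and a
softmax output.  All layers are NumPy with hand-written backprop;
training is full-batch Adam with a fixed seed, so single-threaded runs
are bit-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._optim import Adam
from .errors import DivergenceError, ShapeError, ValidationError
from .volume_io import SummaryStack

__all__ = [
    "CNNConfig",
    "CNNModel",
    "NodeFeatureMatrix",
    "build_model",
    "train",
    "encode",
]


@dataclass(frozen=True)
class CNNConfig:
    input_shape: tuple[int, int, int, int] = (61, 73, 61, 19)  # x,y,z,channels
    first_block_filters: int = 16
    repeated_blocks: int = 4  # filters 32, 64, 128, 256
    repeated_start_filters: int = 32
    dense_units: int = 1024
    dropout: float = 0.5
    seed: int = 0
    epochs: int = 30
    learning_rate: float = 1e-3
    n_classes: int = 2

    @property
    def block_filters(self) -> tuple[int, ...]:
        reps = tuple(
            self.repeated_start_filters * 2**i for i in range(self.repeated_blocks)
        )
        return (self.first_block_filters,) + reps


@dataclass
class NodeFeatureMatrix:
    """(N x dense_units) node features with subject identifiers."""

    values: np.ndarray
    subject_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _conv3d_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """3D cross-correlation with same padding.

    x: (N, C, D, H, W); w: (F, C, kd, kh, kw) with odd kernel dims.
    Implemented as a sum over kernel offsets to keep memory flat.
    """
    kd, kh, kw = w.shape[2:]
    pd, ph, pw = kd // 2, kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    n, c, d, h, wd = x.shape
    out = np.zeros((n, w.shape[0], d, h, wd))
    for a, b, g in itertools.product(range(kd), range(kh), range(kw)):
        sl = xp[:, :, a : a + d, b : b + h, g : g + wd]
        out += np.einsum("fc,ncdhw->nfdhw", w[:, :, a, b, g], sl, optimize=True)
    return out


class _Conv3D:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: tuple[int, int, int] = (3, 3, 3)):
        fan_in = c_in * int(np.prod(kernel))
        self.w = rng.standard_normal((c_out, c_in) + kernel) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(c_out)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return _conv3d_same(x, self.w) + self.b[None, :, None, None, None]

    def backward(self, delta: np.ndarray) -> np.ndarray:
        x = self._x
        kd, kh, kw = self.w.shape[2:]
        pd, ph, pw = kd // 2, kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        n, c, d, h, wd = x.shape
        self.gw = np.zeros_like(self.w)
        for a, b, g in itertools.product(range(kd), range(kh), range(kw)):
            sl = xp[:, :, a : a + d, b : b + h, g : g + wd]
            self.gw[:, :, a, b, g] = np.einsum(
                "nfdhw,ncdhw->fc", delta, sl, optimize=True
            )
        self.gb = delta.sum(axis=(0, 2, 3, 4))
        # input gradient: correlate delta with the flipped, transposed kernel
        w_t = self.w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        return _conv3d_same(delta, w_t)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]


class _ReLU:
    def forward(self, x, training):
        self._m = x > 0
        return x * self._m

    def backward(self, delta):
        return delta * self._m

    def params(self):
        return []

    def grads(self):
        return []


class _BatchNorm3D:
    """Per-channel batch normalisation over (N, D, H, W)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mean
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mean, var = self.run_mean, self.run_var
        shp = (1, -1, 1, 1, 1)
        self._xhat = (x - mean.reshape(shp)) / np.sqrt(var.reshape(shp) + self.eps)
        self._var = var
        self._n = x.shape[0] * x.shape[2] * x.shape[3] * x.shape[4]
        self._training = training
        return self.gamma.reshape(shp) * self._xhat + self.beta.reshape(shp)

    def backward(self, delta):
        shp = (1, -1, 1, 1, 1)
        axes = (0, 2, 3, 4)
        xhat = self._xhat
        self.ggamma = (delta * xhat).sum(axis=axes)
        self.gbeta = delta.sum(axis=axes)
        inv_sd = 1.0 / np.sqrt(self._var + self.eps)
        if not self._training:
            return delta * (self.gamma * inv_sd).reshape(shp)
        n = self._n
        dxhat = delta * self.gamma.reshape(shp)
        return (
            inv_sd.reshape(shp)
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=axes).reshape(shp)
                - xhat * (dxhat * xhat).sum(axis=axes).reshape(shp)
            )
        )

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.ggamma, self.gbeta]


class _MaxPool3D:
    """2x2x2 max-pooling, valid (odd trailing voxels are dropped)."""

    def forward(self, x, training):
        n, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        crop = x[:, :, : 2 * d2, : 2 * h2, : 2 * w2]
        win = crop.reshape(n, c, d2, 2, h2, 2, w2, 2)
        win = win.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, d2, h2, w2, 8)
        self._idx = win.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(win, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, delta):
        n, c, d, h, w = self._in_shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        grad_win = np.zeros((n, c, d2, h2, w2, 8))
        np.put_along_axis(grad_win, self._idx[..., None], delta[..., None], axis=-1)
        grad = grad_win.reshape(n, c, d2, h2, w2, 2, 2, 2).transpose(
            0, 1, 2, 5, 3, 6, 4, 7
        ).reshape(n, c, 2 * d2, 2 * h2, 2 * w2)
        out = np.zeros(self._in_shape)
        out[:, :, : 2 * d2, : 2 * h2, : 2 * w2] = grad
        return out

    def params(self):
        return []

    def grads(self):
        return []


class _GlobalAvgPool:
    def forward(self, x, training):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, delta):
        n, c, d, h, w = self._shape
        return np.broadcast_to(
            delta[:, :, None, None, None], self._shape
        ) / (d * h * w)

    def params(self):
        return []

    def grads(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x, training):
        self._x = x
        return x @ self.w + self.b

    def backward(self, delta):
        self.gw = self._x.T @ delta
        self.gb = delta.sum(axis=0)
        return delta @ self.w.T

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]


class _Dropout:
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, delta):
        return delta if self._mask is None else delta * self._mask

    def params(self):
        return []

    def grads(self):
        return []


class _ReLUFlat(_ReLU):
    pass


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class CNNModel:
    cfg: CNNConfig
    layers: list = field(default_factory=list)
    feature_layer: int = -1  # index of the dense-ReLU activation layer
    summary: list[tuple[str, tuple]] = field(default_factory=list)
    train_log: dict = field(default_factory=dict)

    def forward(self, x: np.ndarray, training: bool, upto: int | None = None):
        for layer in self.layers[:upto]:
            x = layer.forward(x, training)
        return x

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]


def build_model(cfg: CNNConfig = CNNConfig()) -> CNNModel:
    """Assemble the network and a per-layer output-shape summary.

    Raises :class:`ShapeError` if the spatial grid collapses before the
    final pooling stage.
    """
    x, y, z, channels = cfg.input_shape
    rng = np.random.default_rng(cfg.seed)
    layers: list = []
    summary: list[tuple[str, tuple]] = [("input", (x, y, z, channels))]
    d, h, w = x, y, z
    c_in = channels
    for bi, c_out in enumerate(cfg.block_filters):
        layers += [
            _Conv3D(c_in, c_out, rng),
            _ReLU(),
            _BatchNorm3D(c_out),
            _MaxPool3D(),
        ]
        d, h, w = d // 2, h // 2, w // 2
        if min(d, h, w) < 1:
            raise ShapeError(
                f"input {cfg.input_shape[:3]} too small: spatial grid "
                f"vanishes at pooling stage {bi + 1}"
            )
        summary.append((f"block{bi + 1}_conv{c_out}_pool", (d, h, w, c_out)))
        c_in = c_out
    layers.append(_GlobalAvgPool())
    summary.append(("global_avg_pool", (c_in,)))
    layers.append(_Dense(c_in, cfg.dense_units, rng))
    layers.append(_ReLUFlat())
    summary.append(("dense_relu", (cfg.dense_units,)))
    feature_layer = len(layers)  # encode() runs layers[:feature_layer]
    layers.append(_Dropout(cfg.dropout, rng))
    layers.append(_Dense(cfg.dense_units, cfg.n_classes, rng))
    summary.append(("softmax", (cfg.n_classes,)))
    return CNNModel(
        cfg=cfg, layers=layers, feature_layer=feature_layer, summary=summary
    )


def _stacks_to_batch(stacks: list[SummaryStack], cfg: CNNConfig) -> np.ndarray:
    xs = []
    for s in stacks:
        if s.n_channels != cfg.input_shape[3]:
            raise ShapeError(
                f"stack has {s.n_channels} channels, model expects "
                f"{cfg.input_shape[3]}"
            )
        if s.data.shape[:3] != cfg.input_shape[:3]:
            raise ShapeError(
                f"stack grid {s.data.shape[:3]} != model grid "
                f"{cfg.input_shape[:3]}"
            )
        xs.append(np.moveaxis(s.data, 3, 0))  # (C, D, H, W)
    return np.stack(xs)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def train(
    model: CNNModel,
    stacks: list[SummaryStack],
    labels: np.ndarray,
    cfg: CNNConfig | None = None,
) -> CNNModel:
    """Supervised cross-entropy training (full batch, Adam, seeded)."""
    cfg = cfg or model.cfg
    labels = np.asarray(labels)
    for cls in range(cfg.n_classes):
        if (labels == cls).sum() < 2:
            raise ValidationError("need at least 2 training subjects per class")
    x = _stacks_to_batch(stacks, cfg)
    n = x.shape[0]
    onehot = np.zeros((n, cfg.n_classes))
    onehot[np.arange(n), labels] = 1.0
    opt = Adam(model.params(), lr=cfg.learning_rate)
    log = {"loss": [], "accuracy": []}
    for _ in range(cfg.epochs):
        logits = model.forward(x, training=True)
        probs = _softmax(logits)
        loss = float(
            -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean()
        )
        if not np.isfinite(loss):
            raise DivergenceError("CNN training loss became non-finite")
        log["loss"].append(loss)
        log["accuracy"].append(float((probs.argmax(axis=1) == labels).mean()))
        delta = (probs - onehot) / n
        for layer in reversed(model.layers):
            delta = layer.backward(delta)
        opt.step(model.grads())
    model.train_log = log
    return model


def encode(
    model: CNNModel,
    stacks: list[SummaryStack],
    subject_ids: list[str] | None = None,
) -> NodeFeatureMatrix:
    """Activations of the penultimate dense layer (dropout inactive)."""
    x = _stacks_to_batch(stacks, model.cfg)
    feats = model.forward(x, training=False, upto=model.feature_layer)
    ids = subject_ids or [f"sub-{i:04d}" for i in range(len(stacks))]
    return NodeFeatureMatrix(values=feats, subject_ids=ids)
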