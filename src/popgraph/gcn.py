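"""Semi-supervised node classification with a graph convolutional net.

Propagation uses the renormalised adjacency

    A_hat = D_bar^{-1/2} (A + I) D_bar^{-1/2},
    entry (i, j) = (A + I)_ij / sqrt((d_i + 1)(d_j + 1)),

with hidden layers H^k = ReLU(A_hat H^{k-1} W^{k-1}) (no biases), a
final linear layer and a row-wise softmax.  Defaults follow the model
configuration: two 16-unit hidden layers with input dropouts 0.005 and
0.4.  Training is full-batch Adam on the cross-entropy of the
train-mask nodes, with Glorot-uniform initialisation; everything is
seeded and single-threaded, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._optim import Adam
from .errors import DivergenceError, ShapeError, ValidationError
from .graph_build import PopulationGraph

__all__ = [
    "GCNConfig",
    "GCNWeights",
    "normalize_adjacency",
    "forward",
    "fit",
    "predict",
]


@dataclass(frozen=True)
class GCNConfig:
    hidden_layers: tuple[int, ...] = (16, 16)
    dropouts: tuple[float, ...] = (0.005, 0.4)
    n_classes: int = 2
    seed: int = 0
    epochs: int = 200
    learning_rate: float = 0.01
    weight_decay: float = 5e-4

    def __post_init__(self) -> None:
        if len(self.dropouts) != len(self.hidden_layers):
            raise ValidationError("one dropout rate per hidden layer required")
        if any(not 0 <= d < 1 for d in self.dropouts):
            raise ValidationError("dropout rates must lie in [0, 1)")


@dataclass
class GCNWeights:
    """Per-layer weight matrices (hidden layers then the output layer)."""

    layers: list[np.ndarray] = field(default_factory=list)


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric renormalisation of a binary, zero-diagonal adjacency."""
    A = np.asarray(A, dtype=np.float64)
    n = A.shape[0]
    if A.shape != (n, n) or not np.array_equal(A, A.T):
        raise ValidationError("adjacency must be square and symmetric")
    if np.diag(A).any():
        raise ValidationError("adjacency must have a zero diagonal")
    a_bar = A + np.eye(n)
    d = a_bar.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return a_bar * np.outer(inv_sqrt, inv_sqrt)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _init_weights(cfg: GCNConfig, n_features: int) -> GCNWeights:
    rng = np.random.default_rng(cfg.seed)
    sizes = (n_features,) + tuple(cfg.hidden_layers) + (cfg.n_classes,)
    layers = []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (n_in + n_out))
        layers.append(rng.uniform(-limit, limit, size=(n_in, n_out)))
    return GCNWeights(layers=layers)


def forward(
    adj: np.ndarray,
    X: np.ndarray,
    weights: GCNWeights,
    cfg: GCNConfig = GCNConfig(),
    training: bool = False,
    rng: np.random.Generator | None = None,
    return_cache: bool = False,
):
    """Class probabilities for every node (rows sum to 1).

    ``adj`` is the already-normalised A_hat.  Dropout multiplies each
    hidden layer's input by a kept/ (1 - rate) mask during training only.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] != adj.shape[0]:
        raise ShapeError("feature rows must match adjacency size")
    if weights.layers[0].shape[0] != X.shape[1]:
        raise ShapeError(
            f"first weight matrix expects {weights.layers[0].shape[0]} "
            f"features, got {X.shape[1]}"
        )
    if training and rng is None:
        rng = np.random.default_rng(cfg.seed)
    h = X
    cache = {"inputs": [], "masks": [], "pre": []}
    for li, w in enumerate(weights.layers[:-1]):
        rate = cfg.dropouts[li]
        if training and rate > 0:
            keep = (rng.random(h.shape) >= rate) / (1.0 - rate)
            h = h * keep
            cache["masks"].append(keep)
        else:
            cache["masks"].append(None)
        cache["inputs"].append(h)
        z = adj @ h @ w
        cache["pre"].append(z)
        h = np.maximum(z, 0.0)
    cache["inputs"].append(h)
    logits = adj @ h @ weights.layers[-1]
    probs = _softmax(logits)
    return (probs, cache) if return_cache else probs


def fit(
    graph: PopulationGraph, cfg: GCNConfig = GCNConfig()
) -> tuple[GCNWeights, dict]:
    """Full-batch training on the train-mask nodes.

    Returns the weights and a log with per-epoch train loss/accuracy.
    """
    labels = np.asarray(graph.labels)
    train = np.asarray(graph.train_mask, dtype=bool)
    y_train = labels[train]
    present = np.unique(y_train[y_train >= 0])
    if present.size < cfg.n_classes:
        raise ValidationError("every class needs at least one training node")
    adj = normalize_adjacency(graph.adjacency)
    X = np.asarray(graph.node_features, dtype=np.float64)
    weights = _init_weights(cfg, X.shape[1])
    opt = Adam(weights.layers, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 1)
    n_train = int(train.sum())
    log: dict = {"loss": [], "accuracy": []}
    onehot = np.zeros((n_train, cfg.n_classes))
    onehot[np.arange(n_train), y_train] = 1.0

    for _ in range(cfg.epochs):
        probs, cache = forward(
            adj, X, weights, cfg, training=True, rng=rng, return_cache=True
        )
        p_train = probs[train]
        loss = float(-np.log(np.clip(p_train[np.arange(n_train), y_train], 1e-12, None)).mean())
        if not np.isfinite(loss):
            raise DivergenceError("training loss became non-finite")
        log["loss"].append(loss)
        log["accuracy"].append(float((p_train.argmax(axis=1) == y_train).mean()))

        # gradient of mean cross-entropy wrt logits, scattered to all nodes
        d_logits = np.zeros_like(probs)
        d_logits[train] = (p_train - onehot) / n_train
        grads: list[np.ndarray] = [None] * len(weights.layers)
        h_last = cache["inputs"][-1]
        # output layer: logits = adj @ h_last @ W_out
        ah = adj @ h_last
        grads[-1] = ah.T @ d_logits
        delta = (adj.T @ d_logits) @ weights.layers[-1].T
        for li in range(len(weights.layers) - 2, -1, -1):
            delta = delta * (cache["pre"][li] > 0)
            h_in = cache["inputs"][li]
            grads[li] = (adj @ h_in).T @ delta
            delta = (adj.T @ delta) @ weights.layers[li].T
            if cache["masks"][li] is not None:
                delta = delta * cache["masks"][li]
        opt.step(grads)
    return weights, log


def predict(
    graph: PopulationGraph,
    weights: GCNWeights,
    cfg: GCNConfig = GCNConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic argmax predictions (ties break toward the lower
    class index) and the class-probability matrix."""
    adj = normalize_adjacency(graph.adjacency)
    probs = forward(adj, graph.node_features, weights, cfg, training=False)
    return probs.argmax(axis=1), probs
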