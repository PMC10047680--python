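"""Fisher-score ranking and stacked-autoencoder compression.

Radiomic feature vectors are ranked by the two-class Fisher criterion,
the top k (default 2000) are kept, and a 4-level stacked autoencoder
(default 2000 -> 1024 -> 512 -> 256 -> 150, sigmoid activations)
compresses each subject to a nonnegative embedding in [0, 1], which the
downstream sqrt-cosine similarity requires.

Training is greedy layer-wise pretraining (each level learns to
reconstruct its input) followed by end-to-end fine-tuning of the full
encoder/decoder under mean squared reconstruction error, all with
seeded NumPy Adam so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._optim import Adam
from .errors import DivergenceError, ShapeError, ValidationError

__all__ = [
    "FisherRanking",
    "SAEModel",
    "fisher_score",
    "select_top_k",
    "sae_fit",
    "sae_encode",
    "DEFAULT_SAE_SIZES",
]

DEFAULT_SAE_SIZES = (2000, 1024, 512, 256, 150)


@dataclass
class FisherRanking:
    """Per-feature Fisher scores and the descending-score order."""

    scores: np.ndarray
    order: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.order = np.asarray(self.order, dtype=np.int64)
        if self.scores.shape != self.order.shape:
            raise ShapeError("scores and order must have equal length")


def fisher_score(X: np.ndarray, y: np.ndarray) -> FisherRanking:
    """Two-class Fisher criterion per feature.

        F_j = sum_c n_c (mu_cj - mu_j)^2 / sum_c n_c sigma^2_cj

    with class-conditional population variances.  Features whose
    denominator is 0 score 0.  Ties in the ranking break toward the
    lower feature index.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ShapeError("X must be (subjects x features), y one label per row")
    if not np.isfinite(X).all():
        raise ValidationError("X contains missing or non-finite values")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValidationError(f"need exactly 2 classes, got {classes.size}")
    mu = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c in classes:
        xc = X[y == c]
        nc = xc.shape[0]
        if nc < 2:
            raise ValidationError("need at least 2 subjects per class")
        num += nc * (xc.mean(axis=0) - mu) ** 2
        den += nc * xc.var(axis=0)
    # variances below the summation noise floor are numerically zero:
    # a mean of n values of magnitude s carries O(eps * n * s) error
    scale = np.abs(X).max(axis=0)
    floor = X.shape[0] * (np.finfo(float).eps * X.shape[0] * scale) ** 2
    scores = np.zeros(X.shape[1])
    np.divide(num, den, out=scores, where=den > floor)
    # stable sort on -scores preserves ascending index within ties
    order = np.argsort(-scores, kind="stable")
    return FisherRanking(scores=scores, order=order)


def select_top_k(
    ranking: FisherRanking, X: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Keep the k best-ranked feature columns; returns (reduced X, kept
    column indices) for provenance."""
    X = np.asarray(X)
    if k > X.shape[1]:
        raise ValidationError(f"k={k} exceeds {X.shape[1]} features")
    kept = ranking.order[:k]
    return X[:, kept], kept


# ---------------------------------------------------------------------------
# Stacked autoencoder
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class SAEModel:
    """Encoder weights, feature scaling and the training log."""

    layer_sizes: tuple[int, ...]
    enc_w: list[np.ndarray] = field(default_factory=list)
    enc_b: list[np.ndarray] = field(default_factory=list)
    dec_w: list[np.ndarray] = field(default_factory=list)
    dec_b: list[np.ndarray] = field(default_factory=list)
    x_min: np.ndarray | None = None
    x_range: np.ndarray | None = None
    pretrain_losses: list[list[float]] = field(default_factory=list)
    finetune_losses: list[float] = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return len(self.layer_sizes) - 1

    @property
    def output_dim(self) -> int:
        return self.layer_sizes[-1]


def _encode_scaled(model: SAEModel, h: np.ndarray) -> np.ndarray:
    for w, b in zip(model.enc_w, model.enc_b):
        h = _sigmoid(h @ w + b)
    return h


def _forward_full(model: SAEModel, x: np.ndarray):
    """Forward through encoder then decoder, caching activations."""
    acts = [x]
    h = x
    for w, b in zip(model.enc_w, model.enc_b):
        h = _sigmoid(h @ w + b)
        acts.append(h)
    for w, b in zip(model.dec_w, model.dec_b):
        h = _sigmoid(h @ w + b)
        acts.append(h)
    return h, acts


def sae_fit(
    X: np.ndarray,
    seed: int = 0,
    epochs: int = 200,
    learning_rate: float = 1e-3,
    layer_sizes: tuple[int, ...] | None = None,
    finetune_epochs: int | None = None,
) -> SAEModel:
    """Fit the stacked autoencoder on (subjects x features) data.

    Features are min-max scaled to [0, 1] (constant columns map to 0);
    each level is pretrained to reconstruct its input, then the whole
    stack is fine-tuned end to end.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ShapeError("X must be 2D (subjects x features)")
    if X.shape[0] < 8:
        raise ValidationError("need at least 8 subjects to fit the SAE")
    if layer_sizes is None:
        layer_sizes = (X.shape[1],) + DEFAULT_SAE_SIZES[1:]
    if layer_sizes[0] != X.shape[1]:
        raise ShapeError(
            f"layer_sizes[0]={layer_sizes[0]} != n_features={X.shape[1]}"
        )
    if finetune_epochs is None:
        finetune_epochs = epochs
    rng = np.random.default_rng(seed)

    x_min = X.min(axis=0)
    x_range = X.max(axis=0) - x_min
    xs = np.zeros_like(X)
    np.divide(X - x_min, x_range, out=xs, where=x_range > 0)

    model = SAEModel(layer_sizes=tuple(layer_sizes), x_min=x_min, x_range=x_range)

    def _init(n_in: int, n_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-limit, limit, size=(n_in, n_out))

    # greedy layer-wise pretraining
    h = xs
    for lvl in range(model.n_levels):
        n_in, n_out = layer_sizes[lvl], layer_sizes[lvl + 1]
        w1, b1 = _init(n_in, n_out), np.zeros(n_out)
        w2, b2 = _init(n_out, n_in), np.zeros(n_in)
        opt = Adam([w1, b1, w2, b2], lr=learning_rate)
        log: list[float] = []
        for _ in range(epochs):
            z = _sigmoid(h @ w1 + b1)
            r = _sigmoid(z @ w2 + b2)
            diff = r - h
            loss = float((diff**2).mean())
            if not np.isfinite(loss):
                raise DivergenceError(
                    "pretraining loss diverged; try a smaller learning_rate"
                )
            log.append(loss)
            n = h.shape[0] * h.shape[1]
            d_r = 2.0 * diff / n * r * (1 - r)
            g_w2 = z.T @ d_r
            g_b2 = d_r.sum(axis=0)
            d_z = d_r @ w2.T * z * (1 - z)
            g_w1 = h.T @ d_z
            g_b1 = d_z.sum(axis=0)
            opt.step([g_w1, g_b1, g_w2, g_b2])
        model.pretrain_losses.append(log)
        model.enc_w.append(w1)
        model.enc_b.append(b1)
        model.dec_w.insert(0, w2)
        model.dec_b.insert(0, b2)
        h = _sigmoid(h @ w1 + b1)

    # end-to-end fine-tuning
    params = model.enc_w + model.enc_b + model.dec_w + model.dec_b
    opt = Adam(params, lr=learning_rate)
    nl = model.n_levels
    for _ in range(finetune_epochs):
        r, acts = _forward_full(model, xs)
        diff = r - xs
        loss = float((diff**2).mean())
        if not np.isfinite(loss):
            raise DivergenceError(
                "fine-tuning loss diverged; try a smaller learning_rate"
            )
        model.finetune_losses.append(loss)
        n = xs.shape[0] * xs.shape[1]
        grads_w = [None] * (2 * nl)
        grads_b = [None] * (2 * nl)
        delta = 2.0 * diff / n
        # backprop decoder then encoder; activation sigmoid everywhere
        for li in range(2 * nl - 1, -1, -1):
            a_out = acts[li + 1]
            a_in = acts[li]
            d = delta * a_out * (1 - a_out)
            grads_w[li] = a_in.T @ d
            grads_b[li] = d.sum(axis=0)
            w = (model.enc_w + model.dec_w)[li]
            delta = d @ w.T
        grads = (
            grads_w[:nl] + grads_b[:nl] + grads_w[nl:] + grads_b[nl:]
        )
        opt.step(grads)
    return model


def sae_encode(model: SAEModel, X: np.ndarray) -> np.ndarray:
    """Forward pass through the encoder only; outputs lie in [0, 1]."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.layer_sizes[0]:
        raise ShapeError(
            f"expected (n x {model.layer_sizes[0]}) input, got {X.shape}"
        )
    xs = np.zeros_like(X)
    np.divide(X - model.x_min, model.x_range, out=xs, where=model.x_range > 0)
    return _encode_scaled(model, xs)
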