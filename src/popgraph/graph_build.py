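"""Population-graph construction from structural embeddings.

Subjects are nodes; edges come from the improved sqrt-cosine
(Hellinger-style) similarity between their nonnegative embedding
vectors,

    Sim(x, y) = sum_i sqrt(x_i y_i) / (sqrt(sum_i x_i) * sqrt(sum_i y_i)),

thresholded at tau = the minimum over rows of the largest off-diagonal
similarity in that row.  By construction every node keeps at least one
neighbour.  A ``literal_form`` flag evaluates the plain-product variant
(sum x_i y_i / (sum x_i * sum y_i)) for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeError, ValidationError

__all__ = [
    "SimilarityMatrix",
    "PopulationGraph",
    "sqrt_cosine",
    "similarity_matrix",
    "threshold_adjacency",
]


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity with its row-max-minimum threshold."""

    S: np.ndarray
    threshold: float


@dataclass
class PopulationGraph:
    """Binary symmetric adjacency, node features, labels and split masks."""

    adjacency: np.ndarray
    node_features: np.ndarray
    labels: np.ndarray
    train_mask: np.ndarray
    test_mask: np.ndarray
    similarity: SimilarityMatrix | None = None
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        n = a.shape[0]
        if a.shape != (n, n) or not np.array_equal(a, a.T):
            raise ShapeError("adjacency must be square and symmetric")
        if np.diag(a).any():
            raise ValidationError("adjacency diagonal must be zero")
        if self.node_features.shape[0] != n:
            raise ShapeError("one feature row per node required")
        if self.train_mask.shape != (n,) or self.test_mask.shape != (n,):
            raise ShapeError("masks must be length-N boolean vectors")
        if (self.train_mask & self.test_mask).any():
            raise ValidationError("train and test masks must be disjoint")


def _check_nonneg(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if (x < 0).any():
        raise ValidationError(f"{name} must be elementwise nonnegative")
    if x.sum() <= 0:
        raise ValidationError(f"{name} must have a positive sum")
    return x


def sqrt_cosine(
    x: np.ndarray, y: np.ndarray, literal_form: bool = False
) -> float:
    """Improved sqrt-cosine similarity of two nonnegative vectors; lies
    in [0, 1] with Sim(x, x) = 1."""
    x = _check_nonneg(x, "x")
    y = _check_nonneg(y, "y")
    if x.shape != y.shape:
        raise ShapeError("x and y must have equal length")
    if literal_form:
        return float((x * y).sum() / (x.sum() * y.sum()))
    num = float(np.sqrt(x * y).sum())
    return num / float(np.sqrt(x.sum()) * np.sqrt(y.sum()))


def similarity_matrix(
    E: np.ndarray, literal_form: bool = False
) -> SimilarityMatrix:
    """All-pairs sqrt-cosine similarity of embedding rows.

    tau is the minimum over rows of the maximum off-diagonal entry.
    """
    E = np.asarray(E, dtype=np.float64)
    if E.ndim != 2 or E.shape[0] < 2:
        raise ShapeError("E must be (N >= 2) x F")
    if (E < 0).any():
        raise ValidationError("embeddings must be nonnegative")
    sums = E.sum(axis=1)
    if (sums <= 0).any():
        raise ValidationError("every embedding row needs a positive sum")
    if literal_form:
        s = (E @ E.T) / np.outer(sums, sums)
    else:
        q = np.sqrt(E)
        s = (q @ q.T) / np.outer(np.sqrt(sums), np.sqrt(sums))
    s = np.clip((s + s.T) / 2.0, 0.0, 1.0)
    off = s.copy()
    np.fill_diagonal(off, -np.inf)
    tau = float(off.max(axis=1).min())
    return SimilarityMatrix(S=s, threshold=tau)


def threshold_adjacency(sim: SimilarityMatrix) -> np.ndarray:
    """Binary adjacency: an edge where the off-diagonal similarity is at
    or above tau.  tau's construction guarantees minimum degree >= 1."""
    a = (sim.S >= sim.threshold).astype(np.int8)
    np.fill_diagonal(a, 0)
    return a
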