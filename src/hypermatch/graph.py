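"""Adaptive k-nearest-neighbor (akNN) cell graphs.

Each modality's cells are embedded by PCA and connected by a weighted kNN
graph whose per-cell neighbor count is *adaptive*: starting from an initial
``k`` candidates, cell ``i`` retains only neighbors whose weight exceeds the
closed-form threshold

    t_i = 1 - (mean(w_i1..w_ik) - 1 - delta)^2,      delta <= 0,

so cells in dense, homogeneous neighborhoods (high mean weight, low
threshold) keep many neighbors while cells in sparse or rare populations
keep few. The pruned adjacency is max-symmetrized and normalized with the
GCN operator D^{-1/2}(A + I)D^{-1/2} for message passing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborCandidates",
    "WeightedCellGraph",
    "reduce_dimension",
    "knn_candidates",
    "adaptive_prune",
    "build_adjacency",
    "normalize_adjacency",
    "build_aknn_graph",
]


@dataclass
class NeighborCandidates:
    """Per-cell candidate neighbors with weights sorted descending."""

    indices: np.ndarray  # n x k neighbor indices
    weights: np.ndarray  # n x k weights in [0,1], descending per row
    k: int
    metric_tag: str

    def __post_init__(self) -> None:
        if np.any(np.diff(self.weights, axis=1) > 1e-12):
            raise ValueError("candidate weights must be sorted descending per cell")
        if np.any((self.weights < -1e-12) | (self.weights > 1 + 1e-12)):
            raise ValueError("candidate weights must lie in [0, 1]")
        n = self.indices.shape[0]
        if np.any(self.indices == np.arange(n)[:, None]):
            raise ValueError("self-neighbors are not allowed")


@dataclass
class WeightedCellGraph:
    """Weighted adjacency with adaptive per-cell degrees and its normalized operator."""

    n: int
    adjacency: sp.csr_matrix
    adaptive_k: np.ndarray
    normalized: sp.csr_matrix | None = None


def reduce_dimension(values: np.ndarray, n_components: int) -> np.ndarray:
    """Principal-component scores with a deterministic sign convention.

    Uses a full SVD of the centered matrix; each component is flipped so
    that its largest-magnitude loading entry is positive, removing the sign
    ambiguity of the decomposition.
    """
    values = np.asarray(values, dtype=np.float64)
    n, p = values.shape
    if not (1 <= n_components <= min(n, p)):
        raise ValueError(f"n_components={n_components} outside [1, {min(n, p)}]")
    centered = values - values.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    flip = np.sign(vt[np.arange(n_components), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return (u * s) * flip


def default_n_components(n_cells: int, n_features: int, requested: int | None = None) -> int:
    """Default PCA dimensionality: 100, capped at min(n_cells, n_features) - 1."""
    cap = max(1, min(n_cells, n_features) - 1)
    return min(requested if requested is not None else 100, cap)


def knn_candidates(
    scores: np.ndarray,
    k: int,
    weight_fn: str = "cosine01",
) -> NeighborCandidates:
    """Top-``k`` neighbors per cell under a bounded similarity weight.

    ``cosine01`` maps cosine similarity s to (1+s)/2; ``inv_dist`` maps
    Euclidean distance d to 1/(1+d). Both land in [0,1] with larger values
    meaning stronger correlation between cells.
    """
    scores = np.asarray(scores, dtype=np.float64)
    n = scores.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        logger.warning("k=%d >= n=%d; clipping to %d", k, n, n - 1)
        k = n - 1
    if weight_fn == "cosine01":
        nn = NearestNeighbors(n_neighbors=k + 1, metric="cosine").fit(scores)
        dist, idx = nn.kneighbors(scores)
        weights = (2.0 - dist) / 2.0  # cosine distance = 1 - cos
    elif weight_fn == "inv_dist":
        nn = NearestNeighbors(n_neighbors=k + 1, metric="euclidean").fit(scores)
        dist, idx = nn.kneighbors(scores)
        weights = 1.0 / (1.0 + dist)
    else:
        raise ValueError(f"unknown weight_fn {weight_fn!r}")
    # drop the self column wherever it appears (ties may not put it first)
    keep_idx = np.empty((n, k), dtype=int)
    keep_w = np.empty((n, k), dtype=np.float64)
    for i in range(n):
        mask = idx[i] != i
        if mask.sum() == k + 1:  # self not returned (duplicate points)
            mask[-1] = False
        keep_idx[i] = idx[i][mask][:k]
        keep_w[i] = weights[i][mask][:k]
    keep_w = np.clip(keep_w, 0.0, 1.0)
    return NeighborCandidates(keep_idx, keep_w, k, weight_fn)


def adaptive_prune(
    candidates: NeighborCandidates, delta: float = -0.5
) -> tuple[np.ndarray, list[tuple[int, int, float]]]:
    """Per-cell adaptive neighbor counts and the retained directed edges.

    Cell ``i`` keeps candidates with weight strictly above
    ``1 - (mean_i - 1 - delta)^2`` where ``mean_i`` is the mean of its k
    candidate weights. If no candidate clears the threshold (e.g. all
    weights equal 1), the single top candidate is kept so every cell has
    degree >= 1.
    """
    if delta > 0:
        raise ValueError("delta must be <= 0")
    w = candidates.weights
    means = w.mean(axis=1)
    thresholds = 1.0 - (means - 1.0 - delta) ** 2
    keep_counts = (w > thresholds[:, None]).sum(axis=1)
    keep_counts = np.maximum(keep_counts, 1)  # degenerate fallback: top-1
    edges: list[tuple[int, int, float]] = []
    for i, ki in enumerate(keep_counts):
        for j in range(ki):
            edges.append((i, int(candidates.indices[i, j]), float(w[i, j])))
    return keep_counts.astype(int), edges


def build_adjacency(n: int, edges: list[tuple[int, int, float]],
                    adaptive_k: np.ndarray | None = None) -> WeightedCellGraph:
    """Assemble the symmetric weighted adjacency from retained edges.

    Directed edges are symmetrized by elementwise max, keeping the
    strongest evidence of proximity for each unordered pair; diagonal is 0.
    """
    if edges:
        rows, cols, vals = zip(*edges)
        a = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    else:
        a = sp.csr_matrix((n, n))
    a = a.maximum(a.T).tocsr()
    a.setdiag(0)
    a.eliminate_zeros()
    if adaptive_k is None:
        adaptive_k = np.asarray((a > 0).sum(axis=1)).ravel()
    return WeightedCellGraph(n=n, adjacency=a, adaptive_k=np.asarray(adaptive_k, dtype=int))


def normalize_adjacency(graph: WeightedCellGraph, literal_exponent: bool = False) -> sp.csr_matrix:
    """GCN normalization of the adjacency with self-loops.

    Default: symmetric ``D^{-1/2}(A + I)D^{-1/2}`` with
    ``D_ii = sum_j (A + I)_ij``. ``literal_exponent=True`` switches the
    right factor to ``D^{+1/2}`` (an alternative printed convention; the
    symmetric form is standard for GCN propagation).
    """
    a_hat = graph.adjacency + sp.identity(graph.n, format="csr")
    deg = np.asarray(a_hat.sum(axis=1)).ravel()
    d_left = sp.diags(1.0 / np.sqrt(deg))
    d_right = sp.diags(np.sqrt(deg)) if literal_exponent else sp.diags(1.0 / np.sqrt(deg))
    normalized = (d_left @ a_hat @ d_right).tocsr()
    graph.normalized = normalized
    return normalized


def build_aknn_graph(
    values: np.ndarray,
    k: int = 30,
    delta: float = -0.5,
    weight_fn: str = "cosine01",
    n_components: int | None = None,
    literal_exponent: bool = False,
) -> WeightedCellGraph:
    """End-to-end akNN graph: PCA -> kNN candidates -> adaptive pruning ->
    max-symmetrized adjacency -> normalized operator."""
    values = np.asarray(values, dtype=np.float64)
    n, p = values.shape
    ncomp = default_n_components(n, p, n_components)
    scores = reduce_dimension(values, ncomp)
    cands = knn_candidates(scores, k, weight_fn)
    adaptive_k, edges = adaptive_prune(cands, delta)
    graph = build_adjacency(n, edges, adaptive_k)
    normalize_adjacency(graph, literal_exponent)
    return graph
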