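"""Cross-modality cell matching by p-best linear assignment.

Cells of the smaller (query) modality X are matched to cells of the
reference modality Y by minimizing a correlation-derived distance under
one-to-one assignment constraints. A many-to-many initial matching is
built from ``p`` successive optimal assignments, each round excluding the
pairs already chosen, then filtered by a matching-degree threshold alpha
(always keeping each query cell's best pair). The final matching assigns
each query cell exactly N distinct reference partners by stacking N copies
of the distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "MatchingPairs",
    "correlation_distance",
    "solve_assignment",
    "p_best_matchings",
    "filter_pairs",
    "final_matching",
    "assignment_to_pairs",
]

# column-index perturbation used only to break ties deterministically in
# favor of lower column indices; far below any meaningful distance gap
_TIE_EPS = 1e-9


@dataclass(frozen=True)
class MatchingPairs:
    """Triples (x-cell index, y-cell index, matching degree in [0,1])."""

    x_index: np.ndarray
    y_index: np.ndarray
    degree: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.x_index) == len(self.y_index) == len(self.degree)):
            raise ValueError("triple arrays must have equal length")
        if len(self.degree) and (self.degree.min() < -1e-12 or self.degree.max() > 1 + 1e-12):
            raise ValueError("matching degrees must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.x_index)

    def covers_all(self, nx: int) -> bool:
        return len(np.unique(self.x_index)) == nx

    def partners_of(self, i: int) -> np.ndarray:
        return self.y_index[self.x_index == i]


def correlation_distance(
    x_emb: np.ndarray, y_emb: np.ndarray, literal: bool = False
) -> np.ndarray:
    """Pairwise correlation distance between embedding rows.

    ``d_ij`` is derived from the Pearson correlation of row i of ``x_emb``
    with row j of ``y_emb``. Default maps [-1, 1] onto [0, 1] via
    ``(1 - PCC)/2``; ``literal=True`` uses ``clip(1 - PCC, 0, 1)`` instead.
    Constant rows get PCC defined as 0.
    """
    x_emb = np.asarray(x_emb, dtype=np.float64)
    y_emb = np.asarray(y_emb, dtype=np.float64)
    if x_emb.shape[1] != y_emb.shape[1]:
        raise ValueError("embedding dimensions differ")
    if x_emb.shape[1] < 2:
        raise ValueError("PCC needs embedding dimension >= 2")

    def _standardize(m: np.ndarray) -> np.ndarray:
        c = m - m.mean(axis=1, keepdims=True)
        sd = c.std(axis=1, keepdims=True)
        out = np.divide(c, sd, out=np.zeros_like(c), where=sd > 0)
        return out

    d = x_emb.shape[1]
    pcc = (_standardize(x_emb) @ _standardize(y_emb).T) / d
    pcc = np.clip(pcc, -1.0, 1.0)
    if literal:
        return np.clip(1.0 - pcc, 0.0, 1.0)
    return (1.0 - pcc) / 2.0


def _solve(dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    nx, ny = dist.shape
    if nx > ny:
        raise ValueError(f"infeasible assignment: {nx} rows > {ny} columns")
    # tiny monotone column perturbation -> ties resolve to lowest column index
    tie = _TIE_EPS * (np.arange(ny) / max(ny, 1))
    finite = dist[np.isfinite(dist)]
    scale = float(np.abs(finite).max()) if finite.size else 1.0
    rows, cols = linear_sum_assignment(dist + tie * max(scale, 1.0))
    order = np.argsort(rows)
    return rows[order], cols[order]


def solve_assignment(dist: np.ndarray) -> np.ndarray:
    """Exact rectangular linear assignment minimizing <Pi, D>.

    Returns the binary matrix Pi (nx x ny) with unit row sums and column
    sums <= 1. Ties are broken toward the lowest column index.
    """
    dist = np.asarray(dist, dtype=np.float64)
    rows, cols = _solve(dist)
    pi = np.zeros(dist.shape, dtype=np.int8)
    pi[rows, cols] = 1
    return pi


def assignment_to_pairs(pi: np.ndarray, dist: np.ndarray) -> MatchingPairs:
    """Extract (i, j, d_ij) triples from an assignment matrix."""
    rows, cols = np.nonzero(pi)
    return MatchingPairs(rows, cols, np.asarray(dist, dtype=np.float64)[rows, cols])


def p_best_matchings(dist: np.ndarray, p: int) -> MatchingPairs:
    """Many-to-many matching from ``p`` successive optimal assignments.

    Each round solves the assignment on the current cost matrix, then
    forbids the selected (i, j) cells before the next round, so every query
    cell ends with exactly ``p`` distinct reference partners (p * nx triples
    in total). Matching degrees are taken from the original distances.
    """
    dist = np.asarray(dist, dtype=np.float64)
    nx, ny = dist.shape
    if p < 1:
        raise ValueError("p must be >= 1")
    if p > ny:
        raise ValueError(f"infeasible: p={p} rounds need p <= ny={ny}")
    work = dist.copy()
    xs, ys = [], []
    for _ in range(p):
        rows, cols = _solve(work)
        xs.append(rows)
        ys.append(cols)
        work[rows, cols] = np.inf
    x_idx = np.concatenate(xs)
    y_idx = np.concatenate(ys)
    return MatchingPairs(x_idx, y_idx, dist[x_idx, y_idx])


def filter_pairs(m: MatchingPairs, alpha: float = 0.6) -> MatchingPairs:
    """Matching-degree quality filter.

    Keeps triples with degree <= alpha; a query cell whose every triple
    exceeds alpha retains its single best (minimum-degree) triple, so the
    filter never orphans a cell.
    """
    if alpha <= 0:
        raise ValueError("alpha must be in (0, 1]")
    if len(m) == 0:
        raise ValueError("empty matching")
    keep = m.degree <= alpha
    for i in np.unique(m.x_index):
        sel = m.x_index == i
        if not keep[sel].any():
            best = np.flatnonzero(sel)[np.argmin(m.degree[sel])]
            keep[best] = True
    return MatchingPairs(m.x_index[keep], m.y_index[keep], m.degree[keep])


def final_matching(dist: np.ndarray, N: int = 1) -> tuple[np.ndarray, MatchingPairs]:
    """Final 1-to-N matching.

    For N = 1 this is the plain optimal assignment. For N > 1, N copies of
    the distance matrix are stacked vertically and the stacked assignment is
    solved once; the column-sum constraint then guarantees each query cell N
    pairwise-distinct reference partners. Returns the (N*nx) x ny assignment
    matrix and the folded matching pairs.
    """
    dist = np.asarray(dist, dtype=np.float64)
    nx, ny = dist.shape
    if N < 1:
        raise ValueError("N must be >= 1")
    if N * nx > ny:
        raise ValueError(f"infeasible: N*nx = {N * nx} > ny = {ny}")
    stacked = np.tile(dist, (N, 1))
    pi = solve_assignment(stacked)
    rows, cols = np.nonzero(pi)
    x_idx = rows % nx
    order = np.lexsort((cols, x_idx))
    x_idx, cols = x_idx[order], cols[order]
    return pi, MatchingPairs(x_idx, cols, dist[x_idx, cols])
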