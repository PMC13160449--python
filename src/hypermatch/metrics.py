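"""Integration quality metrics and the nested overall score.

Seven base metrics cover three axes of diagonal-integration quality:

* matching accuracy — ACC (label agreement of matched pairs) and FOSCTTM
  (fraction of other-modality cells closer than the true match; needs
  ground-truth pairing);
* biological conservation — NMI, ARI (graph clustering vs labels, scIB
  protocol) and rescaled cell-type silhouette ASW_label;
* modality mixing — graph connectivity GC and batch silhouette ASW_batch
  (scIB definitions).

The nested scores aggregate them:

    S_bio     = [ACC + (1 - FOSCTTM) * I_paired + NMI + max(0, ARI)
                 + ASW_label] / (4 + I_paired)
    S_batch   = (GC + ASW_batch) / 2
    S_overall = 0.6 * S_bio + 0.4 * S_batch

and are all bounded in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_samples,
    silhouette_score,
)
from sklearn.neighbors import kneighbors_graph

from .matching import MatchingPairs

__all__ = [
    "MetricReport",
    "matching_accuracy",
    "foscttm",
    "clustering_scores",
    "silhouette_scores",
    "graph_connectivity",
    "overall_score",
    "combine_scores",
    "evaluate_integration",
]


@dataclass
class MetricReport:
    """Base metrics plus the nested S_bio / S_batch / S_overall scores."""

    acc: float
    nmi: float
    ari: float
    asw_label: float
    gc: float
    asw_batch: float
    paired: bool
    foscttm: float | None = None
    s_bio: float = 0.0
    s_batch: float = 0.0
    s_overall: float = 0.0

    def as_dict(self) -> dict:
        return asdict(self)


def matching_accuracy(m: MatchingPairs, x_labels: np.ndarray, y_labels: np.ndarray) -> float:
    """Fraction of matched triples whose cell-type labels agree.

    Each triple counts once, so a 1-to-N matching averages over all N * nx
    triples.
    """
    x_labels = np.asarray(x_labels, dtype=object)
    y_labels = np.asarray(y_labels, dtype=object)
    if len(m) == 0:
        raise ValueError("empty matching")
    lx = x_labels[m.x_index]
    ly = y_labels[m.y_index]
    if any(v is None for v in lx) or any(v is None for v in ly):
        raise ValueError("missing cell-type label among matched cells")
    return float(np.mean(lx == ly))


def foscttm(
    x_emb: np.ndarray,
    y_emb: np.ndarray,
    true_pairs: np.ndarray | None = None,
) -> float:
    """Fraction Of Samples Closer Than the True Match, averaged both ways.

    For each cell the fraction of other-modality cells *strictly* closer
    (Euclidean) than its true partner is computed with normalizer
    (n_other - 1), so 0 is perfect alignment and the worst case is exactly
    1. ``true_pairs`` is an (n_pairs, 2) array of (x index, y index) rows;
    by default row i of x pairs with row i of y.
    """
    x_emb = np.asarray(x_emb, dtype=np.float64)
    y_emb = np.asarray(y_emb, dtype=np.float64)
    if true_pairs is None:
        if x_emb.shape[0] != y_emb.shape[0]:
            raise ValueError("no true pairing available for unequal cell counts")
        true_pairs = np.column_stack([np.arange(x_emb.shape[0])] * 2)
    true_pairs = np.asarray(true_pairs, dtype=int)
    xi, yi = true_pairs[:, 0], true_pairs[:, 1]
    # distances from each paired x-cell to ALL y-cells and vice versa
    d_x_to_y = np.linalg.norm(x_emb[xi][:, None, :] - y_emb[None, :, :], axis=2)
    d_y_to_x = np.linalg.norm(y_emb[yi][:, None, :] - x_emb[None, :, :], axis=2)
    ny, nx = y_emb.shape[0], x_emb.shape[0]
    true_dx = d_x_to_y[np.arange(len(xi)), yi]
    true_dy = d_y_to_x[np.arange(len(yi)), xi]
    frac_x = (d_x_to_y < true_dx[:, None]).sum(axis=1) / max(ny - 1, 1)
    frac_y = (d_y_to_x < true_dy[:, None]).sum(axis=1) / max(nx - 1, 1)
    return float((frac_x.mean() + frac_y.mean()) / 2.0)


def _leiden_labels(graph_adj: sp.csr_matrix, resolution: float, seed: int) -> np.ndarray:
    import igraph as ig
    import leidenalg

    sources, targets = graph_adj.nonzero()
    keep = sources < targets
    g = ig.Graph(
        n=graph_adj.shape[0],
        edges=list(zip(sources[keep].tolist(), targets[keep].tolist())),
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        weights=np.asarray(graph_adj[sources[keep], targets[keep]]).ravel().tolist(),
    )
    return np.asarray(part.membership)


def clustering_scores(
    embedding: np.ndarray,
    labels: np.ndarray,
    k_graph: int = 15,
    resolutions: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """NMI and ARI of modularity clustering against cell-type labels.

    Follows the scIB protocol: Leiden community detection on a kNN graph
    over a resolution sweep (0.1 ... 2.0, step 0.1), reporting scores at
    the resolution maximizing NMI.
    """
    labels = np.asarray(labels, dtype=object).astype(str)
    if len(set(labels)) < 2:
        return 0.0, 0.0
    if resolutions is None:
        resolutions = np.arange(0.1, 2.01, 0.1)
    adj = kneighbors_graph(embedding, n_neighbors=min(k_graph, len(labels) - 1),
                           mode="connectivity")
    adj = adj.maximum(adj.T).tocsr()
    best_nmi, best_ari = -1.0, 0.0
    for res in resolutions:
        pred = _leiden_labels(adj, float(res), seed)
        nmi = normalized_mutual_info_score(labels, pred)
        if nmi > best_nmi:
            best_nmi = nmi
            best_ari = adjusted_rand_score(labels, pred)
    return float(best_nmi), float(best_ari)


def silhouette_scores(
    embedding: np.ndarray,
    labels: np.ndarray,
    batch_tags: np.ndarray,
) -> tuple[float, float]:
    """Rescaled silhouettes: cell-type separation and batch mixing.

    ``asw_label = (mean label silhouette + 1) / 2`` in [0, 1];
    ``asw_batch`` computes, within each cell-type group containing both
    batches, the mean of ``1 - |batch silhouette|`` and averages over
    groups (scIB definition; 1 = batches perfectly mixed).
    """
    labels = np.asarray(labels, dtype=object).astype(str)
    batch_tags = np.asarray(batch_tags, dtype=object).astype(str)
    if len(set(labels)) < 2:
        raise ValueError("asw_label needs >= 2 label classes")
    if len(set(batch_tags)) < 2:
        raise ValueError("asw_batch undefined with a single batch")
    asw_label = (silhouette_score(embedding, labels) + 1.0) / 2.0
    per_group: list[float] = []
    for lab in np.unique(labels):
        sel = labels == lab
        if len(set(batch_tags[sel])) < 2:
            continue
        sil = silhouette_samples(embedding[sel], batch_tags[sel])
        per_group.append(float(np.mean(1.0 - np.abs(sil))))
    if not per_group:
        raise ValueError("no cell-type group contains both batches")
    return float(asw_label), float(np.mean(per_group))


def graph_connectivity(
    embedding: np.ndarray,
    labels: np.ndarray,
    k_gc: int = 15,
) -> float:
    """Mean largest-connected-component fraction of each cell type's kNN subgraph.

    1 means every cell type forms a single connected neighborhood in the
    joint embedding; classes of size 1 count as fully connected.
    """
    labels = np.asarray(labels, dtype=object).astype(str)
    fractions = []
    for lab in np.unique(labels):
        sel = np.flatnonzero(labels == lab)
        if len(sel) == 1:
            fractions.append(1.0)
            continue
        sub = embedding[sel]
        adj = kneighbors_graph(sub, n_neighbors=min(k_gc, len(sel) - 1),
                               mode="connectivity")
        adj = adj.maximum(adj.T)
        n_comp, comp = csgraph.connected_components(adj, directed=False)
        largest = np.bincount(comp).max()
        fractions.append(largest / len(sel))
    return float(np.mean(fractions))


def combine_scores(s_bio: float, s_batch: float) -> float:
    """Overall score: 0.6 * S_bio + 0.4 * S_batch."""
    return 0.6 * s_bio + 0.4 * s_batch


def overall_score(
    acc: float,
    nmi: float,
    ari: float,
    asw_label: float,
    gc: float,
    asw_batch: float,
    foscttm_value: float | None = None,
    paired: bool = False,
) -> tuple[float, float, float]:
    """Nested (S_bio, S_batch, S_overall) from the base metrics.

    The FOSCTTM term enters only for paired datasets; the normalizer
    N_bio = 4 + I_paired keeps S_bio in [0, 1] either way, and ARI is
    clipped at 0 before averaging.
    """
    for name, val, lo, hi in [
        ("acc", acc, 0, 1), ("nmi", nmi, 0, 1), ("asw_label", asw_label, 0, 1),
        ("gc", gc, 0, 1), ("asw_batch", asw_batch, 0, 1), ("ari", ari, -1, 1),
    ]:
        if not (lo - 1e-9 <= val <= hi + 1e-9):
            raise ValueError(f"{name}={val} outside [{lo}, {hi}]")
    ind = 1 if paired else 0
    if paired:
        if foscttm_value is None:
            raise ValueError("paired evaluation requires FOSCTTM")
        if not (0 - 1e-9 <= foscttm_value <= 1 + 1e-9):
            raise ValueError(f"foscttm={foscttm_value} outside [0, 1]")
    terms = acc + nmi + max(0.0, ari) + asw_label
    if paired:
        terms += 1.0 - foscttm_value
    s_bio = terms / (4 + ind)
    s_batch = (gc + asw_batch) / 2.0
    return s_bio, s_batch, combine_scores(s_bio, s_batch)


def evaluate_integration(
    x_emb: np.ndarray,
    y_emb: np.ndarray,
    matching: MatchingPairs,
    x_labels: np.ndarray,
    y_labels: np.ndarray,
    true_pairs: np.ndarray | None = None,
    k_graph: int = 15,
    seed: int = 0,
) -> MetricReport:
    """Full metric report on a joint embedding plus matching.

    ``true_pairs`` (ground-truth cross-modal pairing) enables FOSCTTM and
    flags the evaluation as paired.
    """
    acc = matching_accuracy(matching, x_labels, y_labels)
    joint = np.vstack([x_emb, y_emb])
    labels = np.concatenate([np.asarray(x_labels, object), np.asarray(y_labels, object)])
    batches = np.concatenate([
        np.full(x_emb.shape[0], "x", dtype=object),
        np.full(y_emb.shape[0], "y", dtype=object),
    ])
    nmi, ari = clustering_scores(joint, labels, k_graph=k_graph, seed=seed)
    asw_label, asw_batch = silhouette_scores(joint, labels, batches)
    gc = graph_connectivity(joint, labels, k_gc=k_graph)
    paired = true_pairs is not None
    fos = foscttm(x_emb, y_emb, true_pairs) if paired else None
    s_bio, s_batch, s_overall = overall_score(
        acc, nmi, ari, asw_label, gc, asw_batch, fos, paired
    )
    return MetricReport(acc=acc, nmi=nmi, ari=ari, asw_label=asw_label, gc=gc,
                        asw_batch=asw_batch, paired=paired, foscttm=fos,
                        s_bio=s_bio, s_batch=s_batch, s_overall=s_overall)
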