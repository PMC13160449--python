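"""End-to-end integration pipeline and matching-based downstream operations.

The pipeline matches each cell of a query modality X to cells of a
reference modality Y without any paired training data:

1. build per-modality akNN graphs and their normalized operators;
2. encode the linked-feature submatrices with the hypergraph contrastive
   encoder and compute the correlation distance between embeddings;
3. initial many-to-many matching by p-best assignment + degree filter;
4. for t = 1..T: CCA joint embedding conditioned on the current matching,
   re-encode both joint embeddings on the fixed graphs, and (except at
   t = T) re-match and re-filter;
5. final 1-to-N assignment on the last distance matrix;
6. final CCA joint embeddings at dimension r_star conditioned on the
   final matching.

Graphs are built once in stage 1 and reused throughout the loop. All
randomness derives from one master seed fanned out per stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cca import joint_embed
from .encoder import EncoderConfig, train_encoder
from .graph import build_aknn_graph
from .io_linking import FeatureLinkage, ModalityMatrix
from .matching import (
    MatchingPairs,
    correlation_distance,
    filter_pairs,
    final_matching,
    p_best_matchings,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "predict_features",
           "smooth_by_neighbors"]


@dataclass
class PipelineConfig:
    """All pipeline hyperparameters.

    ``T`` outer refinement iterations (T = 0 keeps the initial matching),
    ``k``/``delta`` akNN construction, ``p``/``alpha`` the many-to-many
    matching and its degree filter, ``N`` final partners per query cell,
    ``rx``/``ry``/``r``/``r_star`` the embedding dimensions. The encoder
    sub-config defaults to a 50-epoch budget per call (the pipeline makes
    2 + 2T encoder calls per run).
    """

    T: int = 3
    k: int = 30
    delta: float = -0.5
    n_components: int | None = None
    weight_fn: str = "cosine01"
    encoder: EncoderConfig = field(default_factory=lambda: EncoderConfig(epochs=50))
    p: int = 3
    alpha: float = 0.6
    N: int = 1
    rx: int = 40
    ry: int = 40
    r: int = 20
    r_star: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")


@dataclass
class PipelineResult:
    """Final matching, joint embeddings and per-iteration diagnostics."""

    final_pairs: MatchingPairs
    assignment: np.ndarray
    x_star: np.ndarray
    y_star: np.ndarray
    diagnostics: dict


def _encoder_cfg(base: EncoderConfig, seed: int) -> EncoderConfig:
    return EncoderConfig(L=base.L, K=base.K, tau=base.tau, lam=base.lam,
                         epochs=base.epochs, learning_rate=base.learning_rate,
                         negatives_per_anchor=base.negatives_per_anchor, seed=seed)


def run_pipeline(
    x: ModalityMatrix,
    y: ModalityMatrix,
    linkage: FeatureLinkage,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full integration pipeline; deterministic given the seed."""
    cfg = config or PipelineConfig()
    nx, ny = x.n_cells, y.n_cells
    if nx > ny:
        raise ValueError(f"query modality must be the smaller one: nx={nx} > ny={ny}")
    if cfg.N * nx > ny:
        raise ValueError(f"infeasible 1-to-N matching: N*nx={cfg.N * nx} > ny={ny}")
    if linkage.p_link == 0:
        raise ValueError("empty feature linkage")

    seeds = np.random.SeedSequence(cfg.seed).generate_state(2 + 2 * (cfg.T + 1)) % (2**31)
    logger.info("pipeline seed=%d fan-out=%s", cfg.seed, seeds.tolist())

    x_vals, y_vals = x.dense(), y.dense()
    gx = build_aknn_graph(x_vals, k=cfg.k, delta=cfg.delta,
                          weight_fn=cfg.weight_fn, n_components=cfg.n_components)
    gy = build_aknn_graph(y_vals, k=cfg.k, delta=cfg.delta,
                          weight_fn=cfg.weight_fn, n_components=cfg.n_components)

    x_link = x_vals[:, linkage.x_indices()]
    y_link = y_vals[:, linkage.y_indices()]
    st_x = train_encoder(x_link, gx.normalized, _encoder_cfg(cfg.encoder, int(seeds[0])))
    st_y = train_encoder(y_link, gy.normalized, _encoder_cfg(cfg.encoder, int(seeds[1])))
    dist = correlation_distance(st_x.fused, st_y.fused)
    pairs = filter_pairs(p_best_matchings(dist, cfg.p), cfg.alpha)

    diagnostics = {
        "matching_sizes": [len(pairs)],
        "mean_degree": [float(pairs.degree.mean())],
        "encoder_final_loss": [st_x.loss_trace[-1] if st_x.loss_trace else None,
                               st_y.loss_trace[-1] if st_y.loss_trace else None],
    }

    xr_hat, yr_hat = None, None
    for t in range(1, cfg.T + 1):
        xr, yr, _ = joint_embed(x_vals, y_vals, pairs, cfg.rx, cfg.ry, cfg.r)
        st_x = train_encoder(xr, gx.normalized, _encoder_cfg(cfg.encoder, int(seeds[2 * t])))
        st_y = train_encoder(yr, gy.normalized, _encoder_cfg(cfg.encoder, int(seeds[2 * t + 1])))
        xr_hat, yr_hat = st_x.fused, st_y.fused
        dist = correlation_distance(xr_hat, yr_hat)
        diagnostics["encoder_final_loss"].extend(
            [st_x.loss_trace[-1] if st_x.loss_trace else None,
             st_y.loss_trace[-1] if st_y.loss_trace else None])
        if t == cfg.T:
            break
        pairs = filter_pairs(p_best_matchings(dist, cfg.p), cfg.alpha)
        diagnostics["matching_sizes"].append(len(pairs))
        diagnostics["mean_degree"].append(float(pairs.degree.mean()))

    assignment, final_pairs = final_matching(dist, cfg.N)
    diagnostics["matching_sizes"].append(len(final_pairs))
    diagnostics["mean_degree"].append(float(final_pairs.degree.mean()))

    x_star, y_star, _ = joint_embed(x_vals, y_vals, final_pairs,
                                    cfg.rx, cfg.ry, cfg.r_star)
    return PipelineResult(final_pairs=final_pairs, assignment=assignment,
                          x_star=x_star, y_star=y_star, diagnostics=diagnostics)


def predict_features(
    m_star: MatchingPairs,
    y: ModalityMatrix,
    nx: int,
    weight_by_degree: bool = False,
) -> np.ndarray:
    """Regression-free cross-modality prediction.

    Each query cell's predicted feature profile is the mean of its matched
    reference cells' full feature rows (optionally weighted by
    1 - matching degree). Returns an nx x py matrix in the reference
    feature space.
    """
    if not m_star.covers_all(nx):
        raise ValueError("matching does not cover every query cell")
    y_vals = y.dense()
    pred = np.zeros((nx, y.n_features))
    for i in range(nx):
        sel = m_star.x_index == i
        rows = y_vals[m_star.y_index[sel]]
        if weight_by_degree:
            w = 1.0 - m_star.degree[sel]
            w = w / w.sum() if w.sum() > 0 else np.full(len(rows), 1.0 / len(rows))
            pred[i] = w @ rows
        else:
            pred[i] = rows.mean(axis=0)
    return pred


def smooth_by_neighbors(
    embedding: np.ndarray,
    expression: np.ndarray,
    k_smooth: int = 15,
) -> np.ndarray:
    """kNN smoothing of expression over the joint embedding.

    Each cell's profile becomes the mean over itself and its ``k_smooth``
    nearest embedding neighbors (Euclidean); the aggregation used to
    de-noise weak signals before differential testing.
    """
    from sklearn.neighbors import NearestNeighbors

    embedding = np.asarray(embedding, dtype=np.float64)
    expression = np.asarray(expression, dtype=np.float64)
    n = embedding.shape[0]
    if k_smooth >= n:
        raise ValueError(f"k_smooth={k_smooth} must be < n={n}")
    nn = NearestNeighbors(n_neighbors=k_smooth + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    return expression[idx].mean(axis=1)
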