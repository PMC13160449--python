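"""Hypergraph contrastive encoder H(E, A_bar).

Two message-passing branches are computed per layer l = 1..L from the
shared input E^{(l-1)}:

* local (graph view):      Ebar^{(l)} = A_bar E^{(l-1)},
* global (hypergraph view): Etil^{(l)} = H (H^T E^{(l-1)}),  H = E^{(0)} W,

where W (d x K) is the only learnable parameter: a soft incidence map from
n cells to K virtual hyperedges. The two views of each cell are aligned by
an InfoNCE contrastive loss with temperature tau (local anchors, global
candidates, all other cells as negatives), plus an L2 weight-decay term
lambda ||W||^2. Layer outputs are fused without extra parameters:
E^{(l)} = Ebar^{(l)} + Etil^{(l)} and Ehat = sum_l E^{(l)}.

Training is plain reverse-mode differentiation written out by hand over
this fixed computation graph, optimized with Adam; everything is numpy and
fully deterministic given the seed. The global product is always evaluated
right-to-left through the K-dimensional bottleneck, so no n x n dense
matrix is ever formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "EncoderConfig",
    "EncoderState",
    "local_propagate",
    "global_propagate",
    "contrastive_loss",
    "train_encoder",
    "encode",
]


@dataclass
class EncoderConfig:
    """Hyperparameters of the hypergraph contrastive encoder.

    K is the number of virtual hyperedges, tau the InfoNCE temperature,
    lam the weight-decay coefficient on W. ``negatives_per_anchor`` may be
    "all" (exact loss) or an int for seeded negative subsampling on large n.
    """

    L: int = 2
    K: int = 128
    tau: float = 0.5
    lam: float = 1e-2
    epochs: int = 200
    learning_rate: float = 1e-3
    negatives_per_anchor: int | str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class EncoderState:
    """Trained encoder: incidence weights, per-layer embeddings, fused output."""

    W: np.ndarray
    local_layers: list[np.ndarray]
    global_layers: list[np.ndarray]
    fused: np.ndarray
    loss_trace: list[float] = field(default_factory=list)


def local_propagate(normalized: sp.spmatrix | np.ndarray, prev: np.ndarray) -> np.ndarray:
    """One step of local message passing: A_bar @ prev (no parameters)."""
    if normalized.shape[1] != prev.shape[0]:
        raise ValueError(
            f"operator is {normalized.shape}, embeddings have {prev.shape[0]} rows"
        )
    return np.asarray(normalized @ prev)


def global_propagate(base: np.ndarray, W: np.ndarray, prev: np.ndarray) -> np.ndarray:
    """One step of global hypergraph message passing: H (H^T prev), H = base W.

    Evaluated right-to-left so only n x K and K x d intermediates exist.
    """
    if base.shape[1] != W.shape[0] or base.shape[0] != prev.shape[0]:
        raise ValueError("dimension mismatch between base, W and prev")
    h = base @ W
    return h @ (h.T @ prev)


def _row_normalize(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows scaled to unit norm; zero rows stay zero (cosine sim defined 0)."""
    norms = np.linalg.norm(mat, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    return mat / safe[:, None], norms


def contrastive_loss(
    local_layers: list[np.ndarray],
    global_layers: list[np.ndarray],
    tau: float,
) -> float:
    """InfoNCE loss summed over cells and layers.

    Anchors are local-view rows, candidates global-view rows of the same
    layer; the positive is the same cell, every other cell is a negative:

        Lc = -sum_i sum_l log softmax_j(sim(ebar_i, etil_j)/tau)[j=i].
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if len(local_layers) != len(global_layers):
        raise ValueError("layer counts differ")
    total = 0.0
    for u, v in zip(local_layers, global_layers):
        if u.shape != v.shape:
            raise ValueError("layer shapes differ")
        un, _ = _row_normalize(u)
        vn, _ = _row_normalize(v)
        s = (un @ vn.T) / tau
        m = s.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(s - m).sum(axis=1))
        total += float((lse - np.diag(s)).sum())
    return total


def _cosine_grads(u: np.ndarray, v: np.ndarray, gs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of sum_ij gs_ij * cos(u_i, v_j) w.r.t. u and v.

    Zero-norm rows have zero gradient (their similarity is defined as 0).
    """
    un, nu = _row_normalize(u)
    vn, nv = _row_normalize(v)
    gu_n = gs @ vn          # dL/d(un)
    gv_n = gs.T @ un        # dL/d(vn)
    safe_u = np.where(nu > 0, nu, 1.0)
    safe_v = np.where(nv > 0, nv, 1.0)
    gu = (gu_n - (gu_n * un).sum(axis=1, keepdims=True) * un) / safe_u[:, None]
    gv = (gv_n - (gv_n * vn).sum(axis=1, keepdims=True) * vn) / safe_v[:, None]
    gu[nu == 0] = 0.0
    gv[nv == 0] = 0.0
    return gu, gv


def _forward(base: np.ndarray, normalized, W: np.ndarray, L: int):
    h = base @ W
    inputs = [base]
    locals_, globals_ = [], []
    e_prev = base
    for _ in range(L):
        ebar = np.asarray(normalized @ e_prev)
        etil = h @ (h.T @ e_prev)
        locals_.append(ebar)
        globals_.append(etil)
        e_prev = ebar + etil
        inputs.append(e_prev)
    return h, inputs, locals_, globals_


def _loss_and_grad(
    base: np.ndarray,
    normalized,
    W: np.ndarray,
    cfg: EncoderConfig,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray]:
    """Loss L = Lc + lam ||W||^2 and dL/dW by hand-rolled backprop."""
    n = base.shape[0]
    h, inputs, locals_, globals_ = _forward(base, normalized, W, cfg.L)

    if cfg.negatives_per_anchor == "all" or int(cfg.negatives_per_anchor) >= n - 1:
        neg_cols = None
    else:
        m = int(cfg.negatives_per_anchor)
        neg_cols = rng.integers(0, n, size=(n, m))

    loss = cfg.lam * float((W * W).sum())
    g_h = np.zeros_like(h)
    g_e = np.zeros_like(base)  # dL/dE^{(l)} flowing from deeper layers
    # per-layer loss gradients w.r.t. the branch outputs
    d_locals: list[np.ndarray] = []
    d_globals: list[np.ndarray] = []
    for u, v in zip(locals_, globals_):
        un, _ = _row_normalize(u)
        vn, _ = _row_normalize(v)
        if neg_cols is None:
            s = (un @ vn.T) / cfg.tau
            m_ = s.max(axis=1, keepdims=True)
            p = np.exp(s - m_)
            p /= p.sum(axis=1, keepdims=True)
            lse = m_[:, 0] + np.log(np.exp(s - m_).sum(axis=1))
            loss += float((lse - np.diag(s)).sum())
            gs = p.copy()
            gs[np.arange(n), np.arange(n)] -= 1.0
            gs /= cfg.tau
            gu, gv = _cosine_grads(u, v, gs)
        else:
            # candidate set per anchor: the positive plus sampled negatives
            cols = np.concatenate([np.arange(n)[:, None], neg_cols], axis=1)
            sims = np.einsum("id,ijd->ij", un, vn[cols]) / cfg.tau
            m_ = sims.max(axis=1, keepdims=True)
            p = np.exp(sims - m_)
            p /= p.sum(axis=1, keepdims=True)
            lse = m_[:, 0] + np.log(np.exp(sims - m_).sum(axis=1))
            loss += float((lse - sims[:, 0]).sum())
            gs_dense = np.zeros((n, n))
            coef = p.copy()
            coef[:, 0] -= 1.0
            coef /= cfg.tau
            np.add.at(gs_dense, (np.repeat(np.arange(n), cols.shape[1]), cols.ravel()),
                      coef.ravel())
            gu, gv = _cosine_grads(u, v, gs_dense)
        d_locals.append(gu)
        d_globals.append(gv)

    for l in range(cfg.L - 1, -1, -1):
        g_ebar = d_locals[l] + g_e
        g_etil = d_globals[l] + g_e
        e_in = inputs[l]
        # Etil = H (H^T e_in): grads w.r.t. H and e_in
        g_h += g_etil @ (e_in.T @ h) + e_in @ (g_etil.T @ h)
        g_e = h @ (h.T @ g_etil) + np.asarray(normalized.T @ g_ebar)
    g_w = base.T @ g_h + 2.0 * cfg.lam * W
    # base also feeds layer 1 directly, but base is constant: no further grads
    return loss, g_w


def train_encoder(
    initial: np.ndarray,
    normalized: sp.spmatrix | np.ndarray,
    config: EncoderConfig | None = None,
) -> EncoderState:
    """Train W by Adam on L = Lc + lam ||W||^2 and return the fused embedding.

    W is initialized from a seeded normal scaled by 1/sqrt(n*d), which keeps
    the hyperedge operator H H^T near unit spectral scale at the start.
    With ``epochs=0`` the state is a single forward pass at initialization.
    """
    cfg = config or EncoderConfig()
    base = np.asarray(initial, dtype=np.float64)
    if not np.all(np.isfinite(base)):
        raise ValueError("non-finite entries in initial embeddings")
    n, d = base.shape
    rng = np.random.default_rng(cfg.seed)
    W = rng.standard_normal((d, cfg.K)) / np.sqrt(max(n * d, 1))

    trace: list[float] = []
    m = np.zeros_like(W)
    v = np.zeros_like(W)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    for epoch in range(cfg.epochs):
        loss, g = _loss_and_grad(base, normalized, W, cfg, rng)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        trace.append(loss)
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        mhat = m / (1 - beta1 ** (epoch + 1))
        vhat = v / (1 - beta2 ** (epoch + 1))
        W = W - cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

    _, inputs, locals_, globals_ = _forward(base, normalized, W, cfg.L)
    fused = np.zeros_like(base)
    for ebar, etil in zip(locals_, globals_):
        fused += ebar + etil
    return EncoderState(W=W, local_layers=locals_, global_layers=globals_,
                        fused=fused, loss_trace=trace)


def encode(
    initial: np.ndarray,
    normalized: sp.spmatrix | np.ndarray,
    config: EncoderConfig | None = None,
) -> np.ndarray:
    """Convenience wrapper over :func:`train_encoder` returning only Ehat."""
    return train_encoder(initial, normalized, config).fused
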