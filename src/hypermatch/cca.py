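"""Joint embedding by canonical correlation analysis on matched cells.

The transform C(X, Y, M) reduces each modality to its leading principal
components, treats the matched triples of M as paired samples (an x-cell
with several partners contributes several samples), and fits regularized
CCA loadings maximizing successive correlations between the paired score
rows. All cells of both modalities — matched or not — are then projected
through the loadings into a shared r-dimensional space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .graph import reduce_dimension
from .matching import MatchingPairs

__all__ = ["CcaModel", "fit_cca", "transform", "joint_embed"]


@dataclass
class CcaModel:
    """Fitted CCA: per-modality PCA bases, loadings, canonical correlations."""

    rx: int
    ry: int
    r: int
    Cx: np.ndarray  # rx x r
    Cy: np.ndarray  # ry x r
    canonical_correlations: np.ndarray  # length r, non-increasing, in [0,1]
    x_scores: np.ndarray  # nx x rx PCA scores (cached for transform)
    y_scores: np.ndarray
    x_mean: np.ndarray  # means of the paired samples, for centering
    y_mean: np.ndarray


def _inv_sqrt(mat: np.ndarray) -> np.ndarray:
    vals, vecs = scipy.linalg.eigh(mat)
    vals = np.clip(vals, 1e-12, None)
    return (vecs / np.sqrt(vals)) @ vecs.T


def fit_cca(
    x_values: np.ndarray,
    y_values: np.ndarray,
    m: MatchingPairs,
    rx: int = 40,
    ry: int = 40,
    r: int = 20,
    ridge: float = 1e-4,
    weight_by_degree: bool = False,
) -> CcaModel:
    """Fit CCA loadings on the matched sample pairs.

    Within-set covariances get a small ridge so the fit stays well-posed
    when the number of matched samples approaches r. With
    ``weight_by_degree`` each sample is weighted by (1 - matching degree).
    Sign convention: each Cx column's largest-|entry| is made positive (Cy
    flipped jointly), removing the joint sign ambiguity.
    """
    x_values = np.asarray(x_values, dtype=np.float64)
    y_values = np.asarray(y_values, dtype=np.float64)
    # centered data has rank at most min(n - 1, p)
    rx = max(1, min(rx, x_values.shape[0] - 1, x_values.shape[1]))
    ry = max(1, min(ry, y_values.shape[0] - 1, y_values.shape[1]))
    r = min(r, rx, ry)
    if len(m) < r:
        raise ValueError(f"need at least r={r} matched pairs, got {len(m)}")
    xs = reduce_dimension(x_values, rx)
    ys = reduce_dimension(y_values, ry)
    px = xs[m.x_index]
    py = ys[m.y_index]
    if weight_by_degree:
        w = 1.0 - m.degree
        w = w / w.sum()
    else:
        w = np.full(len(m), 1.0 / len(m))
    x_mean = w @ px
    y_mean = w @ py
    pxc = px - x_mean
    pyc = py - y_mean
    cxx = (pxc * w[:, None]).T @ pxc + ridge * np.eye(rx)
    cyy = (pyc * w[:, None]).T @ pyc + ridge * np.eye(ry)
    cxy = (pxc * w[:, None]).T @ pyc
    wx = _inv_sqrt(cxx)
    wy = _inv_sqrt(cyy)
    u, s, vt = np.linalg.svd(wx @ cxy @ wy)
    cx = wx @ u[:, :r]
    cy = wy @ vt[:r].T
    flip = np.sign(cx[np.abs(cx).argmax(axis=0), np.arange(r)])
    flip[flip == 0] = 1.0
    cx *= flip
    cy *= flip
    return CcaModel(rx=rx, ry=ry, r=r, Cx=cx, Cy=cy,
                    canonical_correlations=np.clip(s[:r], 0.0, 1.0),
                    x_scores=xs, y_scores=ys, x_mean=x_mean, y_mean=y_mean)


def transform(model: CcaModel) -> tuple[np.ndarray, np.ndarray]:
    """Project all cells of both modalities into the joint space.

    Returns (X_r, Y_r) of shapes nx x r and ny x r; centering uses the
    matched-sample means from the fit.
    """
    xr = (model.x_scores - model.x_mean) @ model.Cx
    yr = (model.y_scores - model.y_mean) @ model.Cy
    return xr, yr


def joint_embed(
    x_values: np.ndarray,
    y_values: np.ndarray,
    m: MatchingPairs,
    rx: int = 40,
    ry: int = 40,
    r: int = 20,
    ridge: float = 1e-4,
    weight_by_degree: bool = False,
) -> tuple[np.ndarray, np.ndarray, CcaModel]:
    """Fit-and-transform convenience: (X_r, Y_r) <- C(X, Y, M)."""
    model = fit_cca(x_values, y_values, m, rx, ry, r, ridge, weight_by_degree)
    xr, yr = transform(model)
    return xr, yr, model
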