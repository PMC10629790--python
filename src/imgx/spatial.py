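"""Spatial-autocorrelation utilities: weight matrices and Moran's I."""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.spatial.distance import pdist, squareform

__all__ = ["inverse_distance_weights", "grid_rook_weights", "morans_i", "morans_i_permutation_p"]


def inverse_distance_weights(coords: np.ndarray) -> np.ndarray:
    """Dense weight matrix w_ij = 1/d_ij (w_ii = 0) from point coordinates.

    Raises on duplicate points (infinite weight).
    """
    coords = np.asarray(coords, dtype=float)
    d = squareform(pdist(coords))
    n = len(coords)
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError("duplicate coordinates produce infinite weights; jitter them first")
    W = np.zeros_like(d)
    W[off] = 1.0 / d[off]
    return W


def grid_rook_weights(mask: np.ndarray) -> sparse.csr_matrix:
    """Sparse binary 6-neighbour (rook) adjacency over True voxels of a 3-D mask."""
    mask = np.asarray(mask, dtype=bool)
    idx = -np.ones(mask.shape, dtype=int)
    idx[mask] = np.arange(mask.sum())
    rows, cols = [], []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        a = idx[tuple(sl_a)]
        b = idx[tuple(sl_b)]
        ok = (a >= 0) & (b >= 0)
        rows.append(a[ok])
        cols.append(b[ok])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    n = mask.sum()
    W = sparse.coo_matrix(
        (np.ones(2 * len(r)), (np.r_[r, c], np.r_[c, r])), shape=(n, n)
    )
    return W.tocsr()


def morans_i(values: np.ndarray, W) -> float:
    """Moran's I of ``values`` under weight matrix ``W`` (dense or sparse)."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("Moran's I undefined for a constant field")
    s0 = float(W.sum())
    num = float(z @ (W @ z))
    return n / s0 * num / denom


def morans_i_permutation_p(
    values: np.ndarray, W, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """One-sided (positive autocorrelation) permutation p for Moran's I.

    Random relabelings of the values over locations form the null; p uses the
    (1+k)/(1+n) estimator.
    """
    rng = np.random.default_rng(seed)
    obs = morans_i(values, W)
    x = np.asarray(values, dtype=float)
    exceed = 0
    for _ in range(n_perm):
        exceed += morans_i(rng.permutation(x), W) >= obs
    return obs, (1 + exceed) / (1 + n_perm)
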