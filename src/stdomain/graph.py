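"""Gaussian-kernel spot graph with calibrated bandwidth.

The adjacency is ``A_ij = exp(-d_ij^2 / (2 sigma^2))`` on Euclidean
pixel-coordinate distances, so every spot carries a unit self-loop.  The
bandwidth ``sigma`` is not user-set: it is searched so that the mean over
spots of the row sum of ``A - I`` equals a target (0.5 by default), i.e.
each spot's total affinity to all other spots averages to the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

DEFAULT_TARGET_ROWSUM = 0.5
SIGMA_TOL = 1e-3


def pairwise_distances(pixel_xy: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix from (s, 2) pixel coordinates."""
    xy = np.asarray(pixel_xy, dtype=float)
    if xy.ndim != 2 or xy.shape[0] < 2:
        raise ValueError("need at least two spots with 2-D coordinates")
    D = cdist(xy, xy)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def gaussian_adjacency(D: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-kernel adjacency with exact unit diagonal."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    A = np.exp(-np.asarray(D, dtype=float) ** 2 / (2.0 * sigma**2))
    np.fill_diagonal(A, 1.0)
    return A


def mean_excess_rowsum(A: np.ndarray) -> float:
    """Mean over spots of (row sum of A minus the unit self-loop)."""
    return float((A.sum(axis=1) - np.diag(A)).mean())


def calibrate_sigma(
    D: np.ndarray,
    target: float = DEFAULT_TARGET_ROWSUM,
    tol: float = SIGMA_TOL,
    max_iter: int = 200,
) -> float:
    """Bisect sigma so the mean excess row sum of the adjacency hits target.

    The mean excess row sum is continuous and strictly increasing in sigma
    (from 0 toward s-1), so bisection converges; the returned sigma
    satisfies ``|mean - target| <= tol``.
    """
    D = np.asarray(D, dtype=float)
    if target <= 0:
        raise ValueError("target must be positive")
    s = D.shape[0]
    if s < 2:
        raise ValueError("sigma calibration needs at least two spots")
    d_max = D.max()
    if d_max <= 0:
        raise ValueError("all pairwise distances are zero; target unattainable")

    def f(sigma: float) -> float:
        return mean_excess_rowsum(gaussian_adjacency(D, sigma))

    lo, hi = 1e-6 * d_max, 10.0 * d_max
    while f(hi) < target:
        hi *= 2.0
        if hi > 1e12 * d_max:
            raise ValueError(f"target row sum {target} unattainable (max {s - 1})")
    if f(lo) > target:
        raise ValueError("target row sum below attainable range")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        val = f(mid)
        if abs(val - target) <= tol:
            return mid
        if val < target:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("sigma bisection did not converge")


def normalized_laplacian(A: np.ndarray) -> np.ndarray:
    """Symmetrically normalized Laplacian ``I - Deg^{-1/2} A Deg^{-1/2}``."""
    A = np.asarray(A, dtype=float)
    deg = A.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("adjacency has a non-positive row sum")
    inv_sqrt = 1.0 / np.sqrt(deg)
    L = -A * inv_sqrt[:, None] * inv_sqrt[None, :]
    L[np.diag_indices_from(L)] += 1.0
    return (L + L.T) / 2.0


@dataclass
class SpotGraph:
    """Distance matrix, calibrated adjacency and normalized Laplacian."""

    D: np.ndarray
    A: np.ndarray
    L: np.ndarray
    sigma: float
    target_rowsum: float = DEFAULT_TARGET_ROWSUM


def build_spot_graph(
    pixel_xy: np.ndarray, target_rowsum: float = DEFAULT_TARGET_ROWSUM
) -> SpotGraph:
    """Distances -> sigma search -> adjacency -> Laplacian, in one call."""
    D = pairwise_distances(pixel_xy)
    sigma = calibrate_sigma(D, target=target_rowsum)
    A = gaussian_adjacency(D, sigma)
    L = normalized_laplacian(A)
    return SpotGraph(D=D, A=A, L=L, sigma=sigma, target_rowsum=target_rowsum)
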