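"""Adaptive graph convolution (AGC) pre-clustering.

AGC smooths the PCA feature matrix with the parameter-free low-pass filter
``H_t = (I - L/lambda)^t F`` and, at every order ``t``, spectrally embeds
the smoothed features (top eigenvectors of the linear-kernel similarity
``H Ht^T``), clusters the embedding with k-means and scores the assignment
by its mean intra-cluster distance.  Smoothing stops the first time that
distance increases; the assignment from the preceding iteration is the
pre-clustering result used as pseudo-labels downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .graph import SpotGraph, build_spot_graph

DEFAULT_LAMBDA = 1.5
DEFAULT_EMBED_DIM = 26
DEFAULT_MAX_T = 60


def smooth(F: np.ndarray, L: np.ndarray, lam: float = DEFAULT_LAMBDA, t: int = 1) -> np.ndarray:
    """Apply the low-pass filter ``(I - L/lam)^t`` to F by repeated products."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    if t < 0:
        raise ValueError("t must be non-negative")
    H = np.asarray(F, dtype=float)
    L = np.asarray(L, dtype=float)
    for _ in range(int(t)):
        H = H - (L @ H) / lam
    return H


def _fix_signs(U: np.ndarray) -> np.ndarray:
    U = U.copy()
    for j in range(U.shape[1]):
        col = U[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            U[:, j] = -col
    return U


def spectral_embed(H: np.ndarray, dim: int = DEFAULT_EMBED_DIM) -> np.ndarray:
    """Leading spectral components of the similarity ``H H^T``.

    ``H H^T`` is PSD, so its top eigenvectors are the left singular
    vectors of H; the thin SVD of H yields them without forming the
    s-by-s similarity matrix.  Each eigenvector is scaled by the square
    root of its eigenvalue (the kernel-PCA score convention), so the
    embedding preserves the similarity geometry instead of weighting
    every retained direction equally -- with unit-norm columns the many
    low-variance directions drown the cluster structure.  Columns carry a
    deterministic sign (largest-magnitude entry positive).
    """
    H = np.asarray(H, dtype=float)
    if dim > min(H.shape):
        raise ValueError(
            f"dim={dim} exceeds min(H.shape)={min(H.shape)}; no pad policy"
        )
    U, S, _ = np.linalg.svd(H, full_matrices=False)
    return _fix_signs(U[:, :dim] * S[:dim])


def _relabel_first_occurrence(labels: np.ndarray) -> np.ndarray:
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def kmeans_assign(R: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """k-means labels (k-means++, 10 restarts), relabeled by first occurrence."""
    R = np.asarray(R, dtype=float)
    if n > R.shape[0]:
        raise ValueError(f"n={n} exceeds number of samples {R.shape[0]}")
    km = KMeans(n_clusters=n, n_init=10, random_state=int(seed) % (2**31))
    return _relabel_first_occurrence(km.fit_predict(R))


def intra_cluster_distance(H: np.ndarray, C: np.ndarray) -> float:
    """Mean over clusters of the mean pairwise embedding distance.

    Each cluster with at least two members contributes the average L2
    distance over its ordered member pairs; singleton clusters contribute 0
    (they have no intra pairs).  The result averages over all clusters.
    """
    from scipy.spatial.distance import pdist

    H = np.asarray(H, dtype=float)
    C = np.asarray(C)
    if C.size == 0 or C.size != H.shape[0]:
        raise ValueError("cluster assignment must label every embedding row")
    labels = np.unique(C)
    total = 0.0
    for lab in labels:
        members = H[C == lab]
        m = members.shape[0]
        if m < 2:
            continue
        total += 2.0 * pdist(members).sum() / (m * (m - 1))
    return total / labels.size


@dataclass
class PreClusterResult:
    """AGC output: labels adopted at the best smoothing order."""

    labels: np.ndarray
    stop_t: int
    intra_trace: list[float]
    embeddings_at_stop: np.ndarray  # smoothed features H at the adopted t


def run_agc(
    F: np.ndarray,
    L: np.ndarray,
    n: int,
    seed: int = 0,
    max_t: int = DEFAULT_MAX_T,
    lam: float = DEFAULT_LAMBDA,
    embed_dim: int = DEFAULT_EMBED_DIM,
) -> PreClusterResult:
    """Iterate smoothing orders until the intra-cluster distance rises.

    Returns the assignment of the iteration immediately before the first
    increase; if the trace never increases within ``max_t`` iterations, the
    argmin-distance assignment is returned.  The k-means seed is folded
    with the iteration index so each order is clustered deterministically.
    """
    F = np.asarray(F, dtype=float)
    if n == 1:
        H1 = smooth(F, L, lam, 1)
        labels = np.zeros(F.shape[0], dtype=int)
        return PreClusterResult(
            labels=labels,
            stop_t=1,
            intra_trace=[intra_cluster_distance(H1, labels)],
            embeddings_at_stop=H1,
        )
    dim = int(min(embed_dim, min(F.shape)))
    M = -np.asarray(L, dtype=float) / lam
    M[np.diag_indices_from(M)] += 1.0
    H = F
    trace: list[float] = []
    prev: tuple[np.ndarray, np.ndarray] | None = None  # (labels, H) at t-1
    best: tuple[np.ndarray, np.ndarray, int] | None = None  # argmin so far
    for t in range(1, int(max_t) + 1):
        H = M @ H
        R = spectral_embed(H, dim)
        C_t = kmeans_assign(R, n, seed=(seed + 100003 * t) % (2**31))
        trace.append(intra_cluster_distance(H, C_t))
        if t >= 2 and trace[-1] > trace[-2]:
            labels, H_stop = prev  # type: ignore[misc]
            return PreClusterResult(
                labels=labels,
                stop_t=t - 1,
                intra_trace=trace,
                embeddings_at_stop=H_stop,
            )
        prev = (C_t, H.copy())
        if best is None or trace[-1] < trace[best[2] - 1]:
            best = (C_t, H.copy(), t)
    labels, H_stop, stop_t = best  # type: ignore[misc]
    return PreClusterResult(
        labels=labels, stop_t=stop_t, intra_trace=trace, embeddings_at_stop=H_stop
    )


class AGCPreClusterer(ClusterMixin, BaseEstimator):
    """Sklearn-style front end for AGC pre-clustering.

    Parameters
    ----------
    n_clusters : int
        Pre-specified number of spatial domains.
    lam : float
        Low-pass filter constant (approximation to the largest Laplacian
        eigenvalue); 1.5 by default.
    embed_dim : int
        Dimension of the spectral embedding fed to k-means (26 by default,
        clipped to the feature rank).
    max_t : int
        Cap on smoothing iterations when the intra-cluster distance trace
        never turns upward.
    target_rowsum : float
        Calibration target for the Gaussian adjacency bandwidth.
    random_state : int
        Seed folded into every k-means restart.

    ``fit(X, coords=...)`` takes the (s, k) feature matrix and the (s, 2)
    pixel coordinates; alternatively pass a prebuilt ``graph``.
    """

    def __init__(
        self,
        n_clusters: int = 7,
        lam: float = DEFAULT_LAMBDA,
        embed_dim: int = DEFAULT_EMBED_DIM,
        max_t: int = DEFAULT_MAX_T,
        target_rowsum: float = 0.5,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.lam = lam
        self.embed_dim = embed_dim
        self.max_t = max_t
        self.target_rowsum = target_rowsum
        self.random_state = random_state

    def fit(self, X, y=None, coords=None, graph: SpotGraph | None = None):
        X = np.asarray(X, dtype=float)
        if graph is None:
            if coords is None:
                raise ValueError("provide pixel coordinates or a SpotGraph")
            graph = build_spot_graph(coords, target_rowsum=self.target_rowsum)
        result = run_agc(
            X,
            graph.L,
            self.n_clusters,
            seed=self.random_state,
            max_t=self.max_t,
            lam=self.lam,
            embed_dim=self.embed_dim,
        )
        self.graph_ = graph
        self.sigma_ = graph.sigma
        self.labels_ = result.labels
        self.stop_t_ = result.stop_t
        self.intra_trace_ = result.intra_trace
        self.embedding_ = result.embeddings_at_stop
        return self

    def fit_predict(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).labels_
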