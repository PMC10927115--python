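"""Clustering agreement and internal-quality metrics.

The adjusted Rand index is computed from the contingency table of the two
partitions; silhouette and Davies-Bouldin scores are delegated to
scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Contingency:
    """Cross-tabulation of two labelings over the same spots."""

    table: np.ndarray  # (c_u, c_v) int
    n: int


def contingency(U, V) -> Contingency:
    U = np.asarray(U)
    V = np.asarray(V)
    if U.shape != V.shape or U.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    _, ui = np.unique(U, return_inverse=True)
    _, vi = np.unique(V, return_inverse=True)
    table = np.zeros((ui.max() + 1, vi.max() + 1), dtype=np.int64)
    np.add.at(table, (ui, vi), 1)
    return Contingency(table=table, n=int(U.size))


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x * (x - 1) / 2.0


def ari(U, V) -> float:
    """Adjusted Rand index between two partitions.

    Chance-corrected pair-counting agreement: 1 for identical partitions
    (up to relabeling), ~0 for independent ones.  Requires at least two
    spots.
    """
    ct = contingency(U, V)
    if ct.n < 2:
        raise ValueError("ARI needs at least two spots")
    sum_ij = _comb2(ct.table).sum()
    sum_i = _comb2(ct.table.sum(axis=1)).sum()
    sum_j = _comb2(ct.table.sum(axis=0)).sum()
    total = _comb2(np.array(ct.n))
    expected = sum_i * sum_j / total
    max_index = 0.5 * (sum_i + sum_j)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def silhouette_db(E: np.ndarray, C) -> tuple[float, float]:
    """Silhouette coefficient and Davies-Bouldin score of an assignment."""
    from sklearn.metrics import davies_bouldin_score, silhouette_score

    C = np.asarray(C)
    if np.unique(C).size < 2:
        raise ValueError("internal metrics need at least two clusters")
    E = np.asarray(E, dtype=float)
    return float(silhouette_score(E, C)), float(davies_bouldin_score(E, C))
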