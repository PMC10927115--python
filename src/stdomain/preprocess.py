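"""Filtering, normalization, HVG selection and PCA.

The preprocessing chain mirrors the standard spot-level recipe: drop genes
detected in fewer than 3 spots (and, on dense Stereo-style grids, spots with
fewer than 20 detected genes), library-size normalize each spot to 10,000
counts and take ``ln(1 + .)``, rank genes by binned normalized dispersion to
pick the top 3,000 highly variable genes, and extract principal components
-- 50 for the graph-convolution feature matrix and 15 for the channels of
the virtual image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import SpotDataset

MIN_SPOTS_PER_GENE = 3
MIN_GENES_PER_STEREO_SPOT = 20


@dataclass
class NormalizedExpression:
    """Log-normalized expression matrix with an optional HVG ranking.

    ``hvg_index`` lists gene column indices ordered by decreasing
    normalized dispersion (at most the requested number of genes).
    """

    values: np.ndarray  # (s, g) float
    gene_names: list[str]
    hvg_index: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalized values must be finite")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def hvg_values(self) -> np.ndarray:
        if self.hvg_index is None:
            raise ValueError("no HVG selection present; call select_hvg first")
        return self.values[:, self.hvg_index]


def filter_dataset(d: SpotDataset) -> SpotDataset:
    """Apply detection filters: genes first, then (stereo only) spots.

    Genes detected in fewer than 3 spots are removed; on the stereo
    platform, spots in which fewer than 20 genes remain detected are then
    removed.  Removing stereo spots can push further genes below the
    detection threshold, so the two rules are re-applied (in the same
    order) until stable, which makes the filter idempotent.
    """
    out = d
    while True:
        gene_keep = np.flatnonzero(
            (out.counts > 0).sum(axis=0) >= MIN_SPOTS_PER_GENE
        )
        changed = gene_keep.size != out.n_genes
        out = out.subset(genes=gene_keep)
        if out.platform == "stereo":
            spot_keep = np.flatnonzero(
                (out.counts > 0).sum(axis=1) >= MIN_GENES_PER_STEREO_SPOT
            )
            changed |= spot_keep.size != out.n_spots
            out = out.subset(spots=spot_keep)
        if out.n_spots == 0 or out.n_genes == 0:
            raise ValueError("filtering removed all spots or all genes")
        if not changed:
            return out


def normalize(d: SpotDataset) -> NormalizedExpression:
    """Library-size normalization: ``ln(1 + 1e4 * c / total_spot_count)``.

    The ``+1`` inside the logarithm keeps zero counts finite (log1p
    convention); zero counts map to exactly 0.
    """
    totals = d.counts.sum(axis=1)
    if np.any(totals == 0):
        bad = np.flatnonzero(totals == 0)
        raise ValueError(
            f"{bad.size} spot(s) have zero total counts (first: {bad[0]})"
        )
    scaled = d.counts / totals[:, None] * 1e4
    return NormalizedExpression(
        values=np.log1p(scaled), gene_names=list(d.gene_names)
    )


def dispersion_statistic(values: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Normalized dispersion per gene on back-transformed values.

    Dispersion is variance/mean of ``expm1(values)``; genes are binned by
    mean expression and each dispersion is z-scored within its bin so that
    highly expressed genes do not dominate the ranking.  Bins with fewer
    than two genes (or zero spread) fall back to a centred, unscaled score.
    """
    x = np.expm1(values)
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    n_genes = mean.size
    n_bins = int(min(n_bins, max(1, n_genes)))
    # quantile bins on the mean; duplicate edges collapse for ties
    edges = np.unique(np.quantile(mean, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:
        bin_id = np.zeros(n_genes, dtype=int)
    else:
        bin_id = np.clip(np.searchsorted(edges, mean, side="right") - 1, 0, edges.size - 2)
    z = np.empty(n_genes)
    for b in np.unique(bin_id):
        members = bin_id == b
        d_b = disp[members]
        mu = d_b.mean()
        sd = d_b.std(ddof=1) if d_b.size > 1 else 0.0
        z[members] = (d_b - mu) / sd if sd > 0 else (d_b - mu)
    return z


def select_hvg(e: NormalizedExpression, k: int = 3000) -> NormalizedExpression:
    """Rank genes by normalized dispersion; keep the top ``k`` (clipped).

    Returns a new object sharing the value matrix with ``hvg_index`` set.
    Ties and the ranking are deterministic (stable sort by gene index).
    """
    k = int(min(k, e.n_genes))
    z = dispersion_statistic(e.values)
    order = np.argsort(-z, kind="stable")
    return NormalizedExpression(
        values=e.values, gene_names=e.gene_names, hvg_index=order[:k]
    )


@dataclass
class PcaModel:
    """Fitted PCA: mean vector, orthonormal loadings and per-spot scores.

    The sign of each component is fixed so that its largest-magnitude
    loading is positive, making the decomposition deterministic.  ``project``
    maps arbitrary gene vectors (e.g. an all-zero expression profile) into
    the component space.
    """

    mean_vector: np.ndarray  # (g_scope,)
    loadings: np.ndarray  # (g_scope, k), orthonormal columns
    scores: np.ndarray  # (s, k)
    k: int

    def project(self, vectors: np.ndarray) -> np.ndarray:
        v = np.asarray(vectors, dtype=float)
        return (v - self.mean_vector) @ self.loadings


def fit_pca(e: NormalizedExpression, k: int, gene_scope: str = "hvg") -> PcaModel:
    """Fit PCA with ``k`` components on all genes or the HVG subset."""
    from sklearn.decomposition import PCA

    if gene_scope == "hvg":
        X = e.hvg_values()
    elif gene_scope == "all":
        X = e.values
    else:
        raise ValueError("gene_scope must be 'all' or 'hvg'")
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(n_spots, n_genes)={min(X.shape)}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    sv = pca.singular_values_
    tol = max(X.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0.0)
    if sv.size and sv[k - 1] <= tol:
        raise ValueError(f"k={k} exceeds the numerical rank of the input")
    loadings = pca.components_.T.copy()  # (g, k)
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(k):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
            scores[:, j] = -scores[:, j]
    return PcaModel(
        mean_vector=pca.mean_.copy(), loadings=loadings, scores=scores, k=k
    )
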