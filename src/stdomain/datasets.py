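"""Spot-level dataset container and I/O.

A :class:`SpotDataset` bundles the UMI count matrix of a spatial
transcriptomics chip with the two coordinate systems such chips carry:
floating-point *pixel* coordinates (positions on the stained image) and
integer *lattice* coordinates (array row/column indices of each spot).
Visium chips stagger spots between successive rows; Stereo-seq bins form a
dense grid.  The platform tag records which geometry applies.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PLATFORMS = ("visium", "stereo")


@dataclass
class SpotDataset:
    """Raw (or filtered) spot-by-gene UMI counts with coordinates.

    Parameters
    ----------
    counts
        Non-negative integer matrix of shape ``(n_spots, n_genes)``.
    spot_ids, gene_names
        Identifiers for rows and columns of ``counts``.
    pixel_xy
        Float array ``(n_spots, 2)`` of image-pixel positions.
    lattice_rc
        Integer array ``(n_spots, 2)`` of 0-based array (row, col) indices.
    in_tissue
        Boolean flags; spots outside tissue are dropped by the loader.
    platform
        Either ``"visium"`` (staggered lattice) or ``"stereo"`` (dense grid).
    """

    counts: np.ndarray
    spot_ids: list[str]
    gene_names: list[str]
    pixel_xy: np.ndarray
    lattice_rc: np.ndarray
    in_tissue: np.ndarray = field(default=None)  # type: ignore[assignment]
    platform: str = "visium"

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D spot-by-gene matrix")
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integer-valued UMI counts")
            self.counts = np.round(self.counts).astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        s = self.counts.shape[0]
        self.pixel_xy = np.asarray(self.pixel_xy, dtype=float)
        self.lattice_rc = np.asarray(self.lattice_rc)
        if not np.issubdtype(self.lattice_rc.dtype, np.integer):
            rc = np.asarray(self.lattice_rc, dtype=float)
            if not np.allclose(rc, np.round(rc)):
                raise ValueError("lattice coordinates must be integers")
            self.lattice_rc = np.round(rc).astype(np.int64)
        if self.pixel_xy.shape != (s, 2):
            raise ValueError(f"pixel_xy must have shape ({s}, 2)")
        if self.lattice_rc.shape != (s, 2):
            raise ValueError(f"lattice_rc must have shape ({s}, 2)")
        if self.lattice_rc.size and self.lattice_rc.min() < 0:
            raise ValueError("lattice coordinates must be non-negative")
        if self.in_tissue is None:
            self.in_tissue = np.ones(s, dtype=bool)
        self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
        if self.in_tissue.shape != (s,):
            raise ValueError(f"in_tissue must have shape ({s},)")
        if self.platform not in PLATFORMS:
            raise ValueError(f"platform must be one of {PLATFORMS}")
        self.spot_ids = [str(x) for x in self.spot_ids]
        self.gene_names = [str(x) for x in self.gene_names]
        if len(self.spot_ids) != s:
            raise ValueError("spot_ids length must match counts rows")
        if len(self.gene_names) != self.counts.shape[1]:
            raise ValueError("gene_names length must match counts columns")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset(self, spots=None, genes=None) -> "SpotDataset":
        """Return a copy restricted to the given spot/gene index arrays."""
        spots = np.arange(self.n_spots) if spots is None else np.asarray(spots)
        genes = np.arange(self.n_genes) if genes is None else np.asarray(genes)
        return replace(
            self,
            counts=self.counts[np.ix_(spots, genes)],
            spot_ids=[self.spot_ids[i] for i in spots],
            gene_names=[self.gene_names[j] for j in genes],
            pixel_xy=self.pixel_xy[spots],
            lattice_rc=self.lattice_rc[spots],
            in_tissue=self.in_tissue[spots],
        )

    def to_anndata(self):
        import anndata as ad

        obs = pd.DataFrame(
            {
                "in_tissue": self.in_tissue.astype(int),
                "array_row": self.lattice_rc[:, 0],
                "array_col": self.lattice_rc[:, 1],
            },
            index=pd.Index(self.spot_ids, name="spot_id"),
        )
        var = pd.DataFrame(index=pd.Index(self.gene_names, name="gene"))
        adata = ad.AnnData(X=self.counts.astype(np.float64), obs=obs, var=var)
        adata.obsm["spatial"] = self.pixel_xy.copy()
        adata.uns["platform"] = self.platform
        return adata

    @classmethod
    def from_anndata(cls, adata, platform: str | None = None) -> "SpotDataset":
        for col in ("array_row", "array_col"):
            if col not in adata.obs:
                raise ValueError(
                    f"missing lattice coordinate column '{col}' in obs"
                )
        if "spatial" not in adata.obsm:
            raise ValueError("missing pixel coordinates: obsm['spatial']")
        if platform is None:
            platform = str(adata.uns.get("platform", "visium"))
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        rc = np.stack(
            [
                np.asarray(adata.obs["array_row"]),
                np.asarray(adata.obs["array_col"]),
            ],
            axis=1,
        )
        in_tissue = (
            np.asarray(adata.obs["in_tissue"]).astype(bool)
            if "in_tissue" in adata.obs
            else None
        )
        return cls(
            counts=np.asarray(X),
            spot_ids=list(adata.obs_names),
            gene_names=list(adata.var_names),
            pixel_xy=np.asarray(adata.obsm["spatial"], dtype=float),
            lattice_rc=normalize_lattice(rc),
            in_tissue=in_tissue,
            platform=platform,
        )

    def write_h5ad(self, path) -> None:
        self.to_anndata().write_h5ad(path)


def normalize_lattice(rc: np.ndarray) -> np.ndarray:
    """Shift lattice (row, col) indices so each axis starts at 0.

    Accepts 1-based (or arbitrarily offset) array coordinates; the stagger
    pattern of a Visium lattice is preserved because both members of a
    column-parity class shift by the same amount.
    """
    rc = np.asarray(rc)
    rc = np.round(np.asarray(rc, dtype=float)).astype(np.int64)
    if rc.size == 0:
        return rc
    return rc - rc.min(axis=0, keepdims=True)


def _load_csv_mtx_dir(path: str, platform: str) -> SpotDataset:
    from scipy.io import mmread

    mtx_path = os.path.join(path, "matrix.mtx")
    coords_path = os.path.join(path, "coords.csv")
    if not os.path.exists(mtx_path):
        raise ValueError(f"missing counts file: {mtx_path}")
    if not os.path.exists(coords_path):
        raise ValueError(f"missing coordinate table: {coords_path}")
    mat = mmread(mtx_path)
    counts = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
    coords = pd.read_csv(coords_path)
    required = ["spot_id", "row", "col", "px", "py"]
    for col in required:
        if col not in coords.columns:
            raise ValueError(f"coordinate table lacks required column '{col}'")
    genes_path = os.path.join(path, "genes.txt")
    if os.path.exists(genes_path):
        with open(genes_path) as fh:
            gene_names = [ln.strip() for ln in fh if ln.strip()]
    else:
        gene_names = [f"gene{j}" for j in range(counts.shape[1])]
    in_tissue = (
        coords["in_tissue"].to_numpy().astype(bool)
        if "in_tissue" in coords.columns
        else None
    )
    rc = normalize_lattice(coords[["row", "col"]].to_numpy())
    return SpotDataset(
        counts=counts,
        spot_ids=list(coords["spot_id"].astype(str)),
        gene_names=gene_names,
        pixel_xy=coords[["px", "py"]].to_numpy(dtype=float),
        lattice_rc=rc,
        in_tissue=in_tissue,
        platform=platform,
    )


def load_spot_dataset(path, platform: str = "visium") -> SpotDataset:
    """Load a :class:`SpotDataset` from an h5ad file or a CSV/MTX directory.

    The directory layout is ``matrix.mtx`` (spots x genes counts),
    ``coords.csv`` with columns ``spot_id,row,col,px,py[,in_tissue]`` and an
    optional ``genes.txt``.  Spots flagged out-of-tissue are excluded.
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        d = _load_csv_mtx_dir(path, platform)
    else:
        import anndata as ad

        d = SpotDataset.from_anndata(ad.read_h5ad(path), platform=platform)
    if not d.in_tissue.all():
        keep = np.flatnonzero(d.in_tissue)
        d = d.subset(spots=keep)
        d.lattice_rc = normalize_lattice(d.lattice_rc)
    return d
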