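"""Synthetic lattice fixtures with planted spatial domains.

The generator emulates both chip geometries: a staggered (Visium-style)
lattice whose spots occupy positions of matching row/column parity, with
pixel coordinates mapped so the six closest neighbors are equidistant, and
a dense (Stereo-style) grid.  Domains are planted as row stripes, annular
arcs (cortex-layer-like) or Voronoi blobs; each domain owns a block of
marker genes whose expected expression is lifted by a fold factor.  Counts
are overdispersed Gamma-Poisson (negative binomial) draws with optional
Bernoulli dropout, reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import SpotDataset

PIXEL_STEP = 10.0  # pixel units per lattice column step
NB_DISPERSION = 0.5  # negative-binomial overdispersion (var = m + disp*m^2)


@dataclass
class FixtureSpec:
    """Study conditions of a synthetic chip.

    Defaults describe the standard recovery fixture: a ~300-spot staggered
    lattice carrying three row stripes, 200 genes with 10 markers per
    domain at 8-fold lift over a base rate of 0.5 expected counts, and 20%
    dropout.
    """

    platform: str = "visium"
    rows: int = 24
    cols: int = 24
    n_domains: int = 3
    layout: str = "stripes"  # stripes | arcs | blobs
    n_genes: int = 200
    markers_per_domain: int = 10
    base_rate: float = 0.5
    marker_lift: float = 8.0
    dropout: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.markers_per_domain * self.n_domains > self.n_genes:
            raise ValueError("not enough genes for the requested markers")


def make_lattice(spec: FixtureSpec) -> SpotDataset:
    """Coordinates-only dataset for the requested geometry.

    Visium lattices occupy positions where column parity equals row parity
    (even rows / even columns convention); the affine pixel map uses a
    sqrt(3) row stretch so orthogonal and diagonal closest neighbors are
    equidistant, as on a hexagonal chip.  Stereo grids are dense with a
    square pixel map.
    """
    rc = []
    for r in range(spec.rows):
        for c in range(spec.cols):
            if spec.platform == "visium" and (c % 2) != (r % 2):
                continue
            rc.append((r, c))
    rc = np.asarray(rc, dtype=np.int64)
    if spec.platform == "visium":
        px = PIXEL_STEP * rc[:, 1]
        py = PIXEL_STEP * np.sqrt(3.0) * rc[:, 0]
    else:
        px = PIXEL_STEP * rc[:, 1]
        py = PIXEL_STEP * rc[:, 0]
    s = rc.shape[0]
    return SpotDataset(
        counts=np.zeros((s, 0), dtype=np.int64),
        spot_ids=[f"spot{r}_{c}" for r, c in rc],
        gene_names=[],
        pixel_xy=np.stack([px, py], axis=1),
        lattice_rc=rc,
        platform=spec.platform,
    )


def domain_labels(spec: FixtureSpec, lattice: SpotDataset) -> np.ndarray:
    """Planted domain label per spot for the requested layout."""
    rc = lattice.lattice_rc
    n = spec.n_domains
    if spec.layout == "stripes":
        edges = np.linspace(0, spec.rows, n + 1)
        return np.clip(np.searchsorted(edges, rc[:, 0], side="right") - 1, 0, n - 1)
    if spec.layout == "arcs":
        radius = np.hypot(rc[:, 0].astype(float), rc[:, 1].astype(float))
        qs = np.quantile(radius, np.linspace(0, 1, n + 1)[1:-1])
        return np.searchsorted(qs, radius, side="right")
    if spec.layout == "blobs":
        rng = np.random.default_rng(spec.seed + 7)
        centers = np.stack(
            [
                rng.uniform(0, spec.rows, size=n),
                rng.uniform(0, spec.cols, size=n),
            ],
            axis=1,
        )
        d = np.linalg.norm(rc[:, None, :] - centers[None, :, :], axis=2)
        return np.argmin(d, axis=1)
    raise ValueError(f"unknown layout '{spec.layout}'")


def simulate_counts(
    spec: FixtureSpec, lattice: SpotDataset | None = None
) -> tuple[SpotDataset, np.ndarray]:
    """Draw marker-structured negative-binomial counts on the lattice.

    Returns the dataset (counts attached) and the planted domain labels.
    Markers of domain d are the gene block [d*m, (d+1)*m); their expected
    count is ``base_rate * marker_lift`` inside the domain, ``base_rate``
    elsewhere.
    """
    if lattice is None:
        lattice = make_lattice(spec)
    labels = domain_labels(spec, lattice)
    s, g = lattice.n_spots, spec.n_genes
    mean = np.full((s, g), float(spec.base_rate))
    m = spec.markers_per_domain
    for d in range(spec.n_domains):
        gene_block = slice(d * m, (d + 1) * m)
        mean[labels == d, gene_block] *= spec.marker_lift
    rng = np.random.default_rng(spec.seed)
    shape = 1.0 / NB_DISPERSION
    lam = rng.gamma(shape, mean / shape)
    counts = rng.poisson(lam)
    if spec.dropout > 0:
        counts[rng.random((s, g)) < spec.dropout] = 0
    d = SpotDataset(
        counts=counts.astype(np.int64),
        spot_ids=list(lattice.spot_ids),
        gene_names=[f"gene{j}" for j in range(g)],
        pixel_xy=lattice.pixel_xy,
        lattice_rc=lattice.lattice_rc,
        in_tissue=lattice.in_tissue,
        platform=spec.platform,
    )
    return d, labels


def write_fixture(spec: FixtureSpec, h5ad_path, labels_csv_path=None) -> None:
    """Emit the fixture as h5ad plus an optional truth-label CSV."""
    import pandas as pd

    d, labels = simulate_counts(spec)
    d.write_h5ad(h5ad_path)
    if labels_csv_path is not None:
        pd.DataFrame({"spot_id": d.spot_ids, "label": labels}).to_csv(
            labels_csv_path, index=False
        )
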