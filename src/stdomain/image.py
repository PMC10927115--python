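"""Virtual-image encoding of the chip lattice.

Each spot becomes one pixel of a 15-channel raster whose channel vector is
the spot's top-15 PC scores.  Raster positions without a spot are *null*
pixels (the stagger gaps of a Visium lattice, holes next to tissue) or
*background* pixels (outside tissue); both carry the projection of an
all-zero expression profile through the same PCA -- the representation a
cell-free location would have.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import SpotDataset
from .preprocess import NormalizedExpression, PcaModel

SPOT, NULL, BACKGROUND = 0, 1, 2
N_CHANNELS = 15


@dataclass
class VirtualImage:
    """15-channel raster with a pixel classification and spot->pixel map."""

    X: np.ndarray  # (15, h, w)
    pixel_class: np.ndarray  # (h, w) int8, values SPOT/NULL/BACKGROUND
    spot_index: np.ndarray  # (s, 2) int, (row, col) pixel of each spot
    platform: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape[1], self.X.shape[2]

    def spot_values(self) -> np.ndarray:
        """Read back the (s, 15) channel vectors at the spot pixels."""
        return self.X[:, self.spot_index[:, 0], self.spot_index[:, 1]].T


def empty_pixel_value(p: PcaModel) -> np.ndarray:
    """Project the all-zero expression profile into the 15-PC space.

    This is the channel vector assigned to every null and background
    pixel: ``(0 - mean) @ loadings``.
    """
    if p.k != N_CHANNELS:
        raise ValueError(f"image PCA must have k={N_CHANNELS}, got k={p.k}")
    return p.project(np.zeros_like(p.mean_vector))


def _discretize_stereo(pixel_xy: np.ndarray) -> np.ndarray:
    """Map stereo pixel coordinates onto an integer grid.

    Coordinates are divided by the smallest positive gap per axis and
    rounded; this recovers the dense bin lattice when bins are regular.
    """
    xy = np.asarray(pixel_xy, dtype=float)
    rc = np.empty((xy.shape[0], 2), dtype=np.int64)
    # image row corresponds to y, column to x
    for axis, out_col in ((1, 0), (0, 1)):
        vals = xy[:, axis]
        uniq = np.unique(vals)
        gaps = np.diff(uniq)
        gaps = gaps[gaps > 1e-12]
        step = gaps.min() if gaps.size else 1.0
        rc[:, out_col] = np.round((vals - vals.min()) / step).astype(np.int64)
    return rc


def _classify_pixels(occupied: np.ndarray) -> np.ndarray:
    """Non-spot pixels with a spot among their 8 neighbors are null."""
    h, w = occupied.shape
    classes = np.full((h, w), BACKGROUND, dtype=np.int8)
    classes[occupied] = SPOT
    padded = np.zeros((h + 2, w + 2), dtype=bool)
    padded[1:-1, 1:-1] = occupied
    neighbor_any = np.zeros((h, w), dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            neighbor_any |= padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
    classes[~occupied & neighbor_any] = NULL
    return classes


def build_image(
    e: NormalizedExpression, d: SpotDataset, p15: PcaModel
) -> VirtualImage:
    """Arrange the 15 PC scores of each spot on the lattice raster.

    Visium spots are placed at their integer lattice coordinates; stereo
    spots at their pixel coordinates discretized to the bin grid.  The
    canvas spans the occupied bounding box (max row/col + 1).
    """
    if p15.k != N_CHANNELS:
        raise ValueError(f"image PCA must have k={N_CHANNELS}, got k={p15.k}")
    scores = p15.scores
    if scores.shape[0] != d.n_spots:
        raise ValueError("PCA scores and dataset disagree on spot count")
    if d.platform == "stereo":
        rc = _discretize_stereo(d.pixel_xy)
    else:
        rc = np.asarray(d.lattice_rc, dtype=np.int64)
    rc = rc - rc.min(axis=0, keepdims=True)
    h, w = int(rc[:, 0].max()) + 1, int(rc[:, 1].max()) + 1
    flat = rc[:, 0] * w + rc[:, 1]
    if np.unique(flat).size != flat.size:
        raise ValueError("two spots map to the same pixel")
    occupied = np.zeros((h, w), dtype=bool)
    occupied[rc[:, 0], rc[:, 1]] = True
    empty = empty_pixel_value(p15)
    X = np.tile(empty[:, None, None], (1, h, w)).astype(float)
    X[:, rc[:, 0], rc[:, 1]] = scores.T
    return VirtualImage(
        X=X,
        pixel_class=_classify_pixels(occupied),
        spot_index=rc,
        platform=d.platform,
    )
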