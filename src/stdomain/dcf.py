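"""Distance-constrained dilated convolution network (DCF).

Two parallel sub-frameworks of four blocks each run over the virtual
image.  The first three blocks of a sub-framework are (constrained conv ->
batch norm -> ReLU) with 100 channels; the last block is a 1x1 convolution
down to the cluster number.  The two output feature images are combined by
fixed platform-specific weights.

The kernels are what make the network lattice-aware:

* Visium (staggered lattice): a 3x3 kernel with dilation 2 (corners fixed
  at zero) plus a 2x2 kernel with dilation 2 whose taps sit at the four
  diagonal offsets (+-1, +-1).  Together the active taps touch exactly a
  spot pixel's 8 closest spot neighbors and itself -- never a null pixel.
* Stereo (dense lattice): an undilated 3x3 kernel plus a 3x3 kernel with
  dilation 2 whose corners *and* center are zero, reaching the 12 closest
  neighbors plus self.

Taps equally distant from the kernel center share a single trainable
scalar per (out-channel, in-channel) pair, so a neighbor's influence
depends only on its distance.  The network stores those per-group scalars
directly and materializes full kernels from them, which keeps the zero and
tying constraints exact at every step by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np

HIDDEN_CHANNELS = 100
IN_CHANNELS = 15
BN_EPS = 1e-5

VISIUM_SUB_WEIGHTS = (0.7, 0.3)  # 3x3 dilated, 2x2 dilated
STEREO_SUB_WEIGHTS = (0.9, 0.1)  # undilated 3x3, dilated 3x3


@dataclass(frozen=True)
class KernelSpec:
    """Geometry and weight-sharing layout of one constrained kernel.

    ``offsets`` are the active tap displacements (row, col) relative to the
    output pixel; ``group_of`` assigns each tap to a tie group (taps in a
    group share one scalar per channel pair); ``zero_offsets`` are the
    positions of the kernel grid that are clamped to zero.
    """

    size: int
    dilation: int
    offsets: tuple[tuple[int, int], ...]
    group_of: tuple[int, ...]
    zero_offsets: tuple[tuple[int, int], ...] = ()

    @property
    def n_groups(self) -> int:
        return max(self.group_of) + 1 if self.group_of else 0

    @property
    def extent(self) -> int:
        all_off = self.offsets + self.zero_offsets
        return max(max(abs(r), abs(c)) for r, c in all_off)

    def grid_offsets(self) -> list[tuple[int, int]]:
        """Displacements of every position of the size x size kernel grid."""
        if self.size == 3:
            base = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 0), (0, 1),
                    (1, -1), (1, 0), (1, 1)]
        elif self.size == 2:
            # a 2x2 kernel with dilation d spans a (d+1)x(d+1) extent;
            # centered (asymmetric padding) its taps sit at (+-d/2, +-d/2)
            half = max(self.dilation // 2, 1)
            return [(-half, -half), (-half, half), (half, -half), (half, half)]
        elif self.size == 1:
            return [(0, 0)]
        else:
            raise ValueError(f"unsupported kernel size {self.size}")
        return [(r * self.dilation, c * self.dilation) for r, c in base]


def _group_by_distance(offsets: list[tuple[int, int]]) -> list[int]:
    """Tie taps by Euclidean distance to the kernel center."""
    d2 = [r * r + c * c for r, c in offsets]
    uniq = sorted(set(d2))
    return [uniq.index(v) for v in d2]


def make_kernel_specs(
    platform: str, tie_weights: bool = True, zero_corners: bool = True
) -> tuple[KernelSpec, KernelSpec]:
    """Kernel pair for a platform; flags expose the ablation variants.

    ``tie_weights=False`` gives every active tap its own parameter;
    ``zero_corners=False`` re-activates the corner taps of the dilated 3x3
    kernels.  The stereo dilated kernel keeps its center zeroed in every
    mode (the undilated branch already covers the center).
    """
    if platform == "visium":
        k3_all = [(r * 2, c * 2) for r in (-1, 0, 1) for c in (-1, 0, 1)]
        corners = [(r, c) for r, c in k3_all if abs(r) == 2 and abs(c) == 2]
        active3 = [o for o in k3_all if zero_corners is False or o not in corners]
        spec3 = KernelSpec(
            size=3,
            dilation=2,
            offsets=tuple(active3),
            group_of=tuple(
                _group_by_distance(active3)
                if tie_weights
                else range(len(active3))
            ),
            zero_offsets=tuple(corners) if zero_corners else (),
        )
        diag = [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        spec2 = KernelSpec(
            size=2,
            dilation=2,
            offsets=tuple(diag),
            group_of=tuple(
                _group_by_distance(diag) if tie_weights else range(len(diag))
            ),
        )
        return spec3, spec2
    if platform == "stereo":
        k1_all = [(r, c) for r in (-1, 0, 1) for c in (-1, 0, 1)]
        spec1 = KernelSpec(
            size=3,
            dilation=1,
            offsets=tuple(k1_all),
            group_of=tuple(
                _group_by_distance(k1_all) if tie_weights else range(len(k1_all))
            ),
        )
        k2_all = [(r * 2, c * 2) for r in (-1, 0, 1) for c in (-1, 0, 1)]
        corners = [(r, c) for r, c in k2_all if abs(r) == 2 and abs(c) == 2]
        zeroed = [(0, 0)] + (corners if zero_corners else [])
        active2 = [o for o in k2_all if o not in zeroed]
        spec2 = KernelSpec(
            size=3,
            dilation=2,
            offsets=tuple(active2),
            group_of=tuple(
                _group_by_distance(active2)
                if tie_weights
                else range(len(active2))
            ),
            zero_offsets=tuple(zeroed),
        )
        return spec1, spec2
    raise ValueError(f"unknown platform '{platform}'")


def sub_framework_weights(platform: str) -> tuple[float, float]:
    if platform == "visium":
        return VISIUM_SUB_WEIGHTS
    if platform == "stereo":
        return STEREO_SUB_WEIGHTS
    raise ValueError(f"unknown platform '{platform}'")


def materialize_kernel(group_w: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Expand per-group scalars into a dense (C_out, C_in, size, size) kernel."""
    grid = spec.grid_offsets()
    n_out, n_in = group_w.shape[1], group_w.shape[2]
    K = np.zeros((n_out, n_in, spec.size, spec.size))
    off2pos = {off: divmod(i, spec.size) for i, off in enumerate(grid)}
    for off, g in zip(spec.offsets, spec.group_of):
        i, j = off2pos[off]
        K[:, :, i, j] = group_w[g]
    return K


def enforce_constraints(weights: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Project a dense kernel tensor onto the constraint set.

    Zeroed positions are set to exactly 0; within each tie group every tap
    is overwritten with the value at the group's first (canonical) tap --
    the "extra trainable parameter" substitution.  Idempotent.
    """
    W = np.array(weights, copy=True)
    grid = spec.grid_offsets()
    off2pos = {off: divmod(i, spec.size) for i, off in enumerate(grid)}
    for off in spec.zero_offsets:
        i, j = off2pos[off]
        W[..., i, j] = 0.0
    for g in range(spec.n_groups):
        members = [off for off, gg in zip(spec.offsets, spec.group_of) if gg == g]
        i0, j0 = off2pos[members[0]]
        canon = W[..., i0, j0]
        for off in members[1:]:
            i, j = off2pos[off]
            W[..., i, j] = canon
    return W


def conv_apply(x, group_w, bias, spec: KernelSpec):
    """Same-size constrained convolution as a sum of shifted channel mixes.

    ``x`` is (C_in, h, w); ``group_w`` is (n_groups, C_out, C_in).  Output
    pixel (i, j) receives ``sum_taps W[group(tap)] @ x[:, i+dr, j+dc]``
    with zero padding at the canvas border.
    """
    c_in, h, w = x.shape[0], x.shape[1], x.shape[2]
    e = spec.extent
    pad = anp.pad(x, ((0, 0), (e, e), (e, e)), "constant")
    out = 0.0
    for (dr, dc), g in zip(spec.offsets, spec.group_of):
        window = pad[:, e + dr : e + dr + h, e + dc : e + dc + w]
        out = out + anp.tensordot(group_w[g], window, axes=([1], [0]))
    return out + bias[:, None, None]


def batch_norm(x, gamma, beta, frozen_stats=None):
    """Per-channel normalization over all pixels of the single image."""
    if frozen_stats is None:
        mean = anp.mean(x, axis=(1, 2), keepdims=True)
        var = anp.var(x, axis=(1, 2), keepdims=True)
    else:
        mean, var = frozen_stats
    xn = (x - mean) / anp.sqrt(var + BN_EPS)
    return gamma[:, None, None] * xn + beta[:, None, None]


def relu(x):
    return anp.maximum(x, 0.0)


@dataclass
class FeatureImage:
    """Network output: feature image O and spot embedding matrix E."""

    O: np.ndarray  # (n, h, w)
    E: np.ndarray  # (s, n)


class DilatedConvNet:
    """The two-branch constrained network, parameterized by tie-group scalars.

    Parameters live in a nested list structure (one list per branch, one
    dict per layer) so the whole tree can be flattened for the optimizer.
    Weight layout per conv layer: ``w`` of shape (n_groups, C_out, C_in)
    plus ``b``; the three hidden blocks also carry batch-norm ``gamma`` /
    ``beta``.
    """

    def __init__(
        self,
        platform: str,
        n_clusters: int,
        in_channels: int = IN_CHANNELS,
        hidden_channels: int = HIDDEN_CHANNELS,
        tie_weights: bool = True,
        zero_corners: bool = True,
        seed: int = 0,
    ):
        self.platform = platform
        self.n_clusters = int(n_clusters)
        self.in_channels = int(in_channels)
        self.hidden_channels = int(hidden_channels)
        self.tie_weights = bool(tie_weights)
        self.zero_corners = bool(zero_corners)
        self.specs = make_kernel_specs(platform, tie_weights, zero_corners)
        self.sub_weights = sub_framework_weights(platform)
        self.one_by_one = KernelSpec(size=1, dilation=1, offsets=((0, 0),), group_of=(0,))
        self.params = self._init_params(seed)

    def _init_params(self, seed: int):
        rng = np.random.default_rng(seed)

        def conv_init(spec: KernelSpec, c_in: int, c_out: int, with_bn: bool):
            bound = 1.0 / np.sqrt(c_in * spec.size * spec.size)
            layer = {
                "w": rng.uniform(-bound, bound, size=(spec.n_groups, c_out, c_in)),
                "b": np.zeros(c_out),
            }
            if with_bn:
                layer["gamma"] = np.ones(c_out)
                layer["beta"] = np.zeros(c_out)
            return layer

        params = []
        for spec in self.specs:
            branch = []
            c_in = self.in_channels
            for _ in range(3):
                branch.append(conv_init(spec, c_in, self.hidden_channels, True))
                c_in = self.hidden_channels
            branch.append(
                conv_init(self.one_by_one, c_in, self.n_clusters, False)
            )
            params.append(branch)
        return params

    def forward(self, params, X, spot_index=None):
        """Run both branches; returns O (and E when spot_index given)."""
        outs = []
        for spec, branch in zip(self.specs, params):
            hcur = X
            for layer in branch[:3]:
                hcur = conv_apply(hcur, layer["w"], layer["b"], spec)
                hcur = batch_norm(hcur, layer["gamma"], layer["beta"])
                hcur = relu(hcur)
            last = branch[3]
            hcur = conv_apply(hcur, last["w"], last["b"], self.one_by_one)
            outs.append(hcur)
        w1, w2 = self.sub_weights
        O = w1 * outs[0] + w2 * outs[1]
        if spot_index is None:
            return O
        E = O[:, spot_index[:, 0], spot_index[:, 1]].T
        return O, E

    def feature_image(self, img) -> FeatureImage:
        """Plain-numpy forward pass over a :class:`VirtualImage`."""
        O, E = self.forward(self.params, img.X, img.spot_index)
        return FeatureImage(O=np.asarray(O), E=np.asarray(E))

    def kernels(self, params=None) -> list[list[np.ndarray]]:
        """Materialized dense kernels per branch and conv layer."""
        params = self.params if params is None else params
        dense = []
        for spec, branch in zip(self.specs, params):
            layers = [materialize_kernel(layer["w"], spec) for layer in branch[:3]]
            layers.append(materialize_kernel(branch[3]["w"], self.one_by_one))
            dense.append(layers)
        return dense

    # -- checkpointing ---------------------------------------------------
    def save(self, path) -> None:
        flat = {}
        for b, branch in enumerate(self.params):
            for l, layer in enumerate(branch):
                for key, val in layer.items():
                    flat[f"b{b}_l{l}_{key}"] = val
        flat["__meta__"] = np.array(
            [
                self.n_clusters,
                self.in_channels,
                self.hidden_channels,
                int(self.tie_weights),
                int(self.zero_corners),
            ]
        )
        np.savez(path, platform=np.array(self.platform), **flat)

    @classmethod
    def load(cls, path) -> "DilatedConvNet":
        data = np.load(path, allow_pickle=False)
        meta = data["__meta__"]
        net = cls(
            platform=str(data["platform"]),
            n_clusters=int(meta[0]),
            in_channels=int(meta[1]),
            hidden_channels=int(meta[2]),
            tie_weights=bool(meta[3]),
            zero_corners=bool(meta[4]),
        )
        for b, branch in enumerate(net.params):
            for l, layer in enumerate(branch):
                for key in list(layer):
                    layer[key] = data[f"b{b}_l{l}_{key}"]
        return net
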