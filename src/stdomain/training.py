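"""Pre-training and self-supervised training of the DCF network.

Pre-training fits the network's softmax output to the AGC pseudo-labels
with plain cross-entropy.  Training then alternates, DEC-style, between a
Student-t soft assignment ``Q`` of spot embeddings to trainable centroids
and a sharpened target ``P`` (refreshed every 4 iterations and treated as
a constant), minimizing

    L_t = 0.78 * KL(P || Q) + 0.71 * CE_highconf + 1.0 * L_continuity

where the cross-entropy runs only over spots whose best assignment
probability exceeds ``q_cut`` (0.5) and the continuity term penalizes
embedding distance between lattice-adjacent spots (orthogonal and diagonal
pairs weighted 0.62 / 0.58 on Visium, 0.62 / 0 on Stereo).  Both phases
stop early when the label structure degenerates (fewer unique labels than
requested, a cluster below 1% of spots) or, on target-refresh iterations,
when fewer than 0.1% of labels changed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.misc import flatten

from .dcf import DilatedConvNet
from .image import VirtualImage

EPS = 1e-12

# loss weights
W_KL = 0.78
W_CE = 0.71
W_CONT = 1.0
W_ORTHO = 0.62
W_DIAG_VISIUM = 0.58
W_DIAG_STEREO = 0.0

LR_PRETRAIN = {"visium": 0.05, "stereo": 0.005}
LR_TRAIN = {"visium": 0.01, "stereo": 0.001}

MAX_PRETRAIN = 200
MAX_TRAIN = 400
P_UPDATE_EVERY = 4
MIN_CLUSTER_FRAC = 0.01
LABEL_CHANGE_TOL = 0.001
Q_CUT = 0.5


@dataclass
class TrainConfig:
    """All knobs of the two training phases (platform defaults applied)."""

    platform: str = "visium"
    q_cut: float = Q_CUT
    w_kl: float = W_KL
    w_ce: float = W_CE
    w_cont: float = W_CONT
    w_ortho: float = W_ORTHO
    w_diag: float | None = None  # platform default when None
    lr_pretrain: float | None = None
    lr_train: float | None = None
    max_pretrain: int = MAX_PRETRAIN
    max_train: int = MAX_TRAIN
    p_update_every: int = P_UPDATE_EVERY
    min_cluster_frac: float = MIN_CLUSTER_FRAC
    label_change_tol: float = LABEL_CHANGE_TOL

    def __post_init__(self):
        if self.w_diag is None:
            self.w_diag = (
                W_DIAG_VISIUM if self.platform == "visium" else W_DIAG_STEREO
            )
        if self.lr_pretrain is None:
            self.lr_pretrain = LR_PRETRAIN[self.platform]
        if self.lr_train is None:
            self.lr_train = LR_TRAIN[self.platform]


@dataclass
class TrainState:
    """Final state of DEC training: centroids, distributions, assignment."""

    mu: np.ndarray
    Q: np.ndarray
    P: np.ndarray
    C: np.ndarray
    iterations: int
    stop_reason: str
    loss_trace: dict = field(default_factory=dict)


def soft_assign(E, mu):
    """Student-t soft assignment of embeddings to centroids (rows sum to 1)."""
    d2 = anp.sum((E[:, None, :] - mu[None, :, :]) ** 2, axis=2)
    inv = 1.0 / (1.0 + d2)
    return inv / anp.sum(inv, axis=1, keepdims=True)


def target_distribution(Q: np.ndarray) -> np.ndarray:
    """Sharpened auxiliary target: square Q, normalize by cluster mass."""
    Q = np.asarray(Q)
    mass = Q.sum(axis=0)
    if np.any(mass <= 0):
        raise ValueError("a cluster has zero total soft-assignment mass")
    W = Q**2 / mass
    return W / W.sum(axis=1, keepdims=True)


def kl_loss(P, Q):
    """``sum_ij p_ij ln(p_ij / q_ij)``; P is a constant target."""
    P = anp.asarray(P)
    return anp.sum(P * (anp.log(P + EPS) - anp.log(Q + EPS)))


def high_conf_ce(Q, q_cut: float = Q_CUT, mask=None, labels=None):
    """Mean ``-ln q`` of the best cluster over high-confidence spots.

    ``mask``/``labels`` may be supplied (as constants) so gradients flow
    only through Q; with ``q_cut=0`` every spot participates.  Returns 0
    when no spot qualifies.
    """
    if mask is None or labels is None:
        Qv = np.asarray(Q)
        labels = np.argmax(Qv, axis=1)
        mask = Qv.max(axis=1) > q_cut
    if not np.any(mask):
        return 0.0
    rows = np.flatnonzero(mask)
    picked = Q[rows, labels[rows]]
    return -anp.mean(anp.log(picked + EPS))


def lattice_pairs(
    spot_index: np.ndarray, platform: str
) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs of closest lattice neighbors, orthogonal and diagonal.

    On the staggered Visium raster the closest same-row/same-column spots
    sit two pixels apart (offsets (0, 2) / (2, 0)) and the diagonal
    neighbors one pixel apart (offsets (1, +-1)); on the dense Stereo grid
    the orthogonal offsets are (0, 1) / (1, 0) and diagonal (1, +-1).
    """
    rc = {(int(r), int(c)): i for i, (r, c) in enumerate(spot_index)}
    if platform == "visium":
        ortho = [(0, 2), (2, 0)]
    else:
        ortho = [(0, 1), (1, 0)]
    diag = [(1, 1), (1, -1)]

    def collect(offsets):
        pairs = []
        for (r, c), i in rc.items():
            for dr, dc in offsets:
                j = rc.get((r + dr, c + dc))
                if j is not None:
                    pairs.append((i, j))
        return (
            np.asarray(pairs, dtype=int)
            if pairs
            else np.empty((0, 2), dtype=int)
        )

    return collect(ortho), collect(diag)


def _mean_pair_distance(E, pairs):
    if pairs.shape[0] == 0:
        return 0.0
    diff = E[pairs[:, 0]] - E[pairs[:, 1]]
    return anp.mean(anp.sqrt(anp.sum(diff**2, axis=1) + EPS))


def continuity_loss(E, pairs_ortho, pairs_diag, w_ortho=W_ORTHO, w_diag=W_DIAG_VISIUM):
    """Weighted mean embedding distance between neighboring spot pairs."""
    return w_ortho * _mean_pair_distance(E, pairs_ortho) + w_diag * _mean_pair_distance(E, pairs_diag)


def total_loss(L1, L2, L3, w_kl=W_KL, w_ce=W_CE, w_cont=W_CONT):
    return w_kl * L1 + w_ce * L2 + w_cont * L3


def stop_check(
    labels: np.ndarray,
    prev_labels: np.ndarray | None,
    n: int,
    min_frac: float = MIN_CLUSTER_FRAC,
    change_tol: float = LABEL_CHANGE_TOL,
    p_updated: bool = False,
) -> str | None:
    """Return the triggered stop condition name, or None to continue."""
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < n:
        return "fewer_unique_labels_than_n"
    if counts.min() < min_frac * labels.size:
        return "cluster_below_min_fraction"
    if p_updated and prev_labels is not None:
        change = np.mean(labels != prev_labels)
        if change < change_tol:
            return "label_change_below_tolerance"
    return None


class Adam:
    """Plain Adam on a flat parameter vector."""

    def __init__(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = self.v = None
        self.t = 0

    def step(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        if self.m is None:
            self.m = np.zeros_like(x)
            self.v = np.zeros_like(x)
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * g
        self.v = self.beta2 * self.v + (1 - self.beta2) * g**2
        mhat = self.m / (1 - self.beta1**self.t)
        vhat = self.v / (1 - self.beta2**self.t)
        return x - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _softmax_ce(E, labels):
    z = E - anp.max(E, axis=1, keepdims=True)
    logp = z - anp.log(anp.sum(anp.exp(z), axis=1, keepdims=True))
    return -anp.mean(logp[anp.arange(E.shape[0]), labels])


def pretrain(
    net: DilatedConvNet,
    img: VirtualImage,
    C0: np.ndarray,
    lr: float | None = None,
    max_iter: int = MAX_PRETRAIN,
    min_frac: float = MIN_CLUSTER_FRAC,
) -> dict:
    """Fit softmax(E) to the AGC pseudo-labels by cross-entropy.

    Updates ``net.params`` in place; returns a history dict with the loss
    trace and the stop reason.  The degenerate-label stop rules also apply
    here (the target-refresh rule does not: no P exists yet).
    """
    C0 = np.asarray(C0, dtype=int)
    s = img.spot_index.shape[0]
    if C0.shape[0] != s:
        raise ValueError("pseudo-label vector length must equal spot count")
    if lr is None:
        lr = LR_PRETRAIN[net.platform]
    X, spot_index = img.X, img.spot_index
    flat, unflatten = flatten(net.params)

    def loss_fn(flat_params):
        params = unflatten(flat_params)
        _, E = net.forward(params, X, spot_index)
        return _softmax_ce(E, C0)

    vag = value_and_grad(loss_fn)
    opt = Adam(lr)
    trace, stop_reason, prev_labels = [], "max_iter", None
    it = 0
    for it in range(1, int(max_iter) + 1):
        val, g = vag(flat)
        flat = opt.step(flat, g)
        trace.append(float(val))
        _, E = net.forward(unflatten(flat), X, spot_index)
        labels = np.argmax(np.asarray(E), axis=1)
        reason = stop_check(labels, prev_labels, net.n_clusters, min_frac)
        prev_labels = labels
        if reason is not None and reason != "label_change_below_tolerance":
            stop_reason = reason
            break
    net.params = unflatten(flat)
    return {"loss": trace, "iterations": it, "stop_reason": stop_reason}


def init_centroids(E: np.ndarray, C0: np.ndarray, n: int) -> np.ndarray:
    """Per-cluster means of the embeddings under the pseudo-labels."""
    E = np.asarray(E)
    mu = np.zeros((n, E.shape[1]))
    for j in range(n):
        members = E[C0 == j]
        mu[j] = members.mean(axis=0) if members.shape[0] else E.mean(axis=0)
    return mu


def train(
    net: DilatedConvNet,
    img: VirtualImage,
    C0: np.ndarray,
    cfg: TrainConfig | None = None,
) -> TrainState:
    """DEC-style self-supervised refinement of the pre-trained network.

    Per iteration: forward -> Q -> (refresh P on iterations 1, 5, 9, ...)
    -> stop check on argmax-Q labels -> composite loss -> Adam step over
    network parameters and centroids.  Returns the final assignment and
    the per-iteration traces of all loss terms.
    """
    cfg = cfg or TrainConfig(platform=net.platform)
    C0 = np.asarray(C0, dtype=int)
    X, spot_index = img.X, img.spot_index
    n = net.n_clusters
    pairs_ortho, pairs_diag = lattice_pairs(spot_index, net.platform)

    _, E0 = net.forward(net.params, X, spot_index)
    mu = init_centroids(np.asarray(E0), C0, n)
    tree = {"net": net.params, "mu": mu}
    flat, unflatten = flatten(tree)
    opt = Adam(cfg.lr_train)

    trace = {"L1": [], "L2": [], "L3": [], "Lt": [], "change_ratio": []}
    P = None
    prev_labels = None
    stop_reason = "max_iter"
    stopped = False
    it = 0
    for it in range(1, int(cfg.max_train) + 1):
        tree = unflatten(flat)
        _, E_det = net.forward(tree["net"], X, spot_index)
        E_det = np.asarray(E_det)
        Q_det = np.asarray(soft_assign(E_det, tree["mu"]))
        p_updated = (it - 1) % cfg.p_update_every == 0
        if p_updated:
            P = target_distribution(Q_det)
        labels = np.argmax(Q_det, axis=1)
        change = (
            float(np.mean(labels != prev_labels))
            if prev_labels is not None
            else 1.0
        )
        trace["change_ratio"].append(change)
        reason = stop_check(
            labels,
            prev_labels,
            n,
            cfg.min_cluster_frac,
            cfg.label_change_tol,
            p_updated,
        )
        prev_labels = labels
        if reason is not None:
            stop_reason = reason
            stopped = True
            break

        hc_mask = Q_det.max(axis=1) > cfg.q_cut
        hc_labels = labels
        P_const = P

        # loss components at the current parameters (plain numpy, no grad)
        L1v = float(kl_loss(P_const, Q_det))
        L2v = float(high_conf_ce(Q_det, cfg.q_cut, mask=hc_mask, labels=hc_labels))
        L3v = float(
            continuity_loss(E_det, pairs_ortho, pairs_diag, cfg.w_ortho, cfg.w_diag)
        )
        trace["L1"].append(L1v)
        trace["L2"].append(L2v)
        trace["L3"].append(L3v)
        trace["Lt"].append(
            float(total_loss(L1v, L2v, L3v, cfg.w_kl, cfg.w_ce, cfg.w_cont))
        )

        def scalar_loss(flat_params):
            tr = unflatten(flat_params)
            _, E = net.forward(tr["net"], X, spot_index)
            Q = soft_assign(E, tr["mu"])
            L1 = kl_loss(P_const, Q)
            L2 = high_conf_ce(Q, cfg.q_cut, mask=hc_mask, labels=hc_labels)
            L3 = continuity_loss(
                E, pairs_ortho, pairs_diag, cfg.w_ortho, cfg.w_diag
            )
            return total_loss(L1, L2, L3, cfg.w_kl, cfg.w_ce, cfg.w_cont)

        _, g = value_and_grad(scalar_loss)(flat)
        flat = opt.step(flat, g)

    tree = unflatten(flat)
    net.params = tree["net"]
    _, E_fin = net.forward(tree["net"], X, spot_index)
    Q_fin = np.asarray(soft_assign(np.asarray(E_fin), tree["mu"]))
    if stopped and prev_labels is not None:
        labels_fin = prev_labels
    else:
        labels_fin = np.argmax(Q_fin, axis=1)
    if P is None:
        P = target_distribution(Q_fin)
    return TrainState(
        mu=tree["mu"],
        Q=Q_fin,
        P=np.asarray(P),
        C=np.asarray(labels_fin),
        iterations=it,
        stop_reason=stop_reason,
        loss_trace=trace,
    )
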