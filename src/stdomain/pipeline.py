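"""End-to-end spatial-domain clustering estimator and pipeline runner."""

from __future__ import annotations

import logging
import os
import time

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .agc import run_agc
from .config import RunConfig
from .datasets import SpotDataset, load_spot_dataset
from .dcf import DilatedConvNet
from .graph import build_spot_graph
from .image import build_image
from .preprocess import NormalizedExpression, fit_pca, filter_dataset, normalize, select_hvg
from .training import TrainConfig, pretrain, train

log = logging.getLogger("stdomain")

# Training-objective and kernel-constraint variants used in the ablation
# comparison; each entry overrides the full objective's switches.
ABLATION_MODES: dict[str, dict] = {
    "full": {},
    "ce+ortho": {"w_kl": 0.0, "q_cut": 0.0, "w_diag": 0.0},
    "ce+ortho+diag": {"w_kl": 0.0, "q_cut": 0.0},
    "hce+ortho+diag": {"w_kl": 0.0},
    "kl+hce+ortho": {"w_diag": 0.0},
    "no_distance": {"tie_weights": False},
    "no_distance+corners": {"tie_weights": False, "zero_corners": False},
}


def ablation_config(mode: str | None) -> dict:
    """Switch overrides for a named ablation mode (case-insensitive)."""
    if mode is None:
        return {}
    key = mode.strip().lower().replace(" ", "")
    if key not in ABLATION_MODES:
        raise ValueError(
            f"unknown ablation mode '{mode}'; choose from {sorted(ABLATION_MODES)}"
        )
    return dict(ABLATION_MODES[key])


class SpatialDomainCluster(ClusterMixin, BaseEstimator):
    """Full spatial-domain clustering: AGC pre-clustering + DCF refinement.

    The estimator runs the whole chain on a spot dataset: detection
    filters, log normalization, HVG selection, PCA (50 components for the
    graph features, 15 for the image channels), Gaussian spot graph with
    calibrated bandwidth, AGC pre-clustering, virtual-image construction,
    and pre-training plus DEC-style training of the constrained dilated
    convolution network.

    Parameters mirror the method's published constants; ``ablation``
    selects one of the named objective/constraint variants.

    ``fit`` accepts a :class:`SpotDataset`, an AnnData object, or a path
    readable by :func:`load_spot_dataset`.

    Attributes (after fit)
    ----------------------
    labels_ : final domain assignment per spot
    precluster_labels_ : AGC pseudo-labels
    sigma_ : calibrated Gaussian bandwidth
    intra_trace_, agc_stop_t_ : AGC diagnostics
    image_, net_ : virtual image and trained network
    pretrain_history_, train_state_ : loss traces and stop reasons
    """

    def __init__(
        self,
        n_clusters: int = 7,
        platform: str = "visium",
        n_hvg: int = 3000,
        n_feature_pcs: int = 50,
        n_image_pcs: int = 15,
        target_rowsum: float = 0.5,
        lam: float = 1.5,
        embed_dim: int = 26,
        max_agc_iter: int = 60,
        hidden_channels: int = 100,
        q_cut: float = 0.5,
        w_kl: float = 0.78,
        w_ce: float = 0.71,
        w_cont: float = 1.0,
        w_ortho: float = 0.62,
        w_diag: float | None = None,
        lr_pretrain: float | None = None,
        lr_train: float | None = None,
        max_pretrain: int = 200,
        max_train: int = 400,
        p_update_every: int = 4,
        min_cluster_frac: float = 0.01,
        label_change_tol: float = 0.001,
        ablation: str | None = None,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.platform = platform
        self.n_hvg = n_hvg
        self.n_feature_pcs = n_feature_pcs
        self.n_image_pcs = n_image_pcs
        self.target_rowsum = target_rowsum
        self.lam = lam
        self.embed_dim = embed_dim
        self.max_agc_iter = max_agc_iter
        self.hidden_channels = hidden_channels
        self.q_cut = q_cut
        self.w_kl = w_kl
        self.w_ce = w_ce
        self.w_cont = w_cont
        self.w_ortho = w_ortho
        self.w_diag = w_diag
        self.lr_pretrain = lr_pretrain
        self.lr_train = lr_train
        self.max_pretrain = max_pretrain
        self.max_train = max_train
        self.p_update_every = p_update_every
        self.min_cluster_frac = min_cluster_frac
        self.label_change_tol = label_change_tol
        self.ablation = ablation
        self.random_state = random_state

    # -- internals -------------------------------------------------------
    def _coerce(self, X) -> SpotDataset:
        if isinstance(X, SpotDataset):
            return X
        if isinstance(X, (str, os.PathLike)):
            return load_spot_dataset(X, platform=self.platform)
        return SpotDataset.from_anndata(X, platform=self.platform)

    def fit(self, X, y=None):
        t0 = time.time()
        d = self._coerce(X)
        d = filter_dataset(d)
        e = normalize(d)
        e = select_hvg(e, self.n_hvg)
        n_hvg_used = e.hvg_index.size
        k50 = int(min(self.n_feature_pcs, d.n_spots - 1, n_hvg_used))
        k15 = int(min(self.n_image_pcs, d.n_spots - 1, n_hvg_used))
        p50 = fit_pca(e, k50, gene_scope="hvg")
        p15 = fit_pca(e, k15, gene_scope="hvg")
        log.info("preprocess: %d spots, %d genes (%d HVG) [%.1fs]",
                 d.n_spots, d.n_genes, n_hvg_used, time.time() - t0)

        t1 = time.time()
        graph = build_spot_graph(d.pixel_xy, target_rowsum=self.target_rowsum)
        log.info("graph: sigma=%.4g [%.1fs]", graph.sigma, time.time() - t1)

        t2 = time.time()
        pre = run_agc(
            p50.scores,
            graph.L,
            self.n_clusters,
            seed=self.random_state,
            max_t=self.max_agc_iter,
            lam=self.lam,
            embed_dim=self.embed_dim,
        )
        log.info("AGC: stop_t=%d [%.1fs]", pre.stop_t, time.time() - t2)

        overrides = ablation_config(self.ablation)
        tie_weights = overrides.pop("tie_weights", True)
        zero_corners = overrides.pop("zero_corners", True)
        cfg = TrainConfig(
            platform=self.platform,
            q_cut=overrides.get("q_cut", self.q_cut),
            w_kl=overrides.get("w_kl", self.w_kl),
            w_ce=overrides.get("w_ce", self.w_ce),
            w_cont=overrides.get("w_cont", self.w_cont),
            w_ortho=overrides.get("w_ortho", self.w_ortho),
            w_diag=overrides.get("w_diag", self.w_diag),
            lr_pretrain=self.lr_pretrain,
            lr_train=self.lr_train,
            max_pretrain=self.max_pretrain,
            max_train=self.max_train,
            p_update_every=self.p_update_every,
            min_cluster_frac=self.min_cluster_frac,
            label_change_tol=self.label_change_tol,
        )

        img = build_image(e, d, p15)
        net = DilatedConvNet(
            platform=self.platform,
            n_clusters=self.n_clusters,
            in_channels=k15,
            hidden_channels=self.hidden_channels,
            tie_weights=tie_weights,
            zero_corners=zero_corners,
            seed=self.random_state,
        )
        t3 = time.time()
        hist = pretrain(
            net, img, pre.labels,
            lr=cfg.lr_pretrain, max_iter=cfg.max_pretrain,
            min_frac=cfg.min_cluster_frac,
        )
        log.info("pretrain: %d iters (%s) [%.1fs]",
                 hist["iterations"], hist["stop_reason"], time.time() - t3)
        t4 = time.time()
        state = train(net, img, pre.labels, cfg)
        log.info("train: %d iters (%s) [%.1fs]",
                 state.iterations, state.stop_reason, time.time() - t4)

        self.dataset_ = d
        self.expression_ = e
        self.pca50_ = p50
        self.pca15_ = p15
        self.graph_ = graph
        self.sigma_ = graph.sigma
        self.precluster_labels_ = pre.labels
        self.agc_stop_t_ = pre.stop_t
        self.intra_trace_ = pre.intra_trace
        self.image_ = img
        self.net_ = net
        self.pretrain_history_ = hist
        self.train_state_ = state
        self.labels_ = state.C
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline from a config; write artifacts; return paths.

    Outputs under ``config.output_dir``: ``labels.csv``, ``clustered.h5ad``
    (labels appended), ``loss_trace.csv``, ``intra_trace.csv`` and, when a
    truth-label CSV is supplied, ``ari_report.txt``.
    """
    import pandas as pd

    from .metrics import ari

    os.makedirs(config.output_dir, exist_ok=True)
    model = SpatialDomainCluster(
        n_clusters=config.n_clusters,
        platform=config.platform,
        n_hvg=config.n_hvg,
        n_feature_pcs=config.n_feature_pcs,
        n_image_pcs=config.n_image_pcs,
        target_rowsum=config.target_rowsum,
        lam=config.lam,
        embed_dim=config.embed_dim,
        max_agc_iter=config.max_agc_iter,
        hidden_channels=config.hidden_channels,
        q_cut=config.q_cut,
        w_kl=config.w_kl,
        w_ce=config.w_ce,
        w_cont=config.w_cont,
        w_ortho=config.w_ortho,
        w_diag=config.w_diag,
        lr_pretrain=config.lr_pretrain,
        lr_train=config.lr_train,
        max_pretrain=config.max_pretrain,
        max_train=config.max_train,
        p_update_every=config.p_update_every,
        min_cluster_frac=config.min_cluster_frac,
        label_change_tol=config.label_change_tol,
        ablation=config.ablation,
        random_state=config.seed,
    )
    model.fit(config.input_path)

    paths = {}
    d = model.dataset_
    labels_df = pd.DataFrame(
        {"spot_id": d.spot_ids, "precluster": model.precluster_labels_,
         "label": model.labels_}
    )
    paths["labels"] = os.path.join(config.output_dir, "labels.csv")
    labels_df.to_csv(paths["labels"], index=False)

    adata = d.to_anndata()
    adata.obs["domain"] = pd.Categorical(model.labels_)
    adata.obs["precluster"] = pd.Categorical(model.precluster_labels_)
    paths["h5ad"] = os.path.join(config.output_dir, "clustered.h5ad")
    adata.write_h5ad(paths["h5ad"])

    trace = model.train_state_.loss_trace
    paths["loss_trace"] = os.path.join(config.output_dir, "loss_trace.csv")
    pd.DataFrame(
        {k: pd.Series(v) for k, v in trace.items()}
    ).to_csv(paths["loss_trace"], index_label="iteration")
    paths["intra_trace"] = os.path.join(config.output_dir, "intra_trace.csv")
    pd.DataFrame({"intra": model.intra_trace_}).to_csv(
        paths["intra_trace"], index_label="t"
    )

    if config.truth_labels:
        truth = pd.read_csv(config.truth_labels)
        truth = truth.rename(columns={truth.columns[-1]: "truth"})
        merged = labels_df.merge(truth[["spot_id", "truth"]], on="spot_id")
        pre_ari = ari(merged["truth"], merged["precluster"])
        fin_ari = ari(merged["truth"], merged["label"])
        paths["ari_report"] = os.path.join(config.output_dir, "ari_report.txt")
        with open(paths["ari_report"], "w") as fh:
            fh.write(
                f"sigma: {model.sigma_:.6g}\n"
                f"precluster_ari: {pre_ari:.4f}\n"
                f"final_ari: {fin_ari:.4f}\n"
            )
    return paths
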