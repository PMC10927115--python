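"""Run configuration: a flat YAML-serializable record of every constant."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class RunConfig:
    """Everything a full clustering run needs, YAML round-trippable."""

    input_path: str = ""
    output_dir: str = "."
    platform: str = "visium"
    n_clusters: int = 7
    truth_labels: str | None = None

    # preprocessing
    n_hvg: int = 3000
    n_feature_pcs: int = 50
    n_image_pcs: int = 15

    # graph + AGC
    target_rowsum: float = 0.5
    lam: float = 1.5
    embed_dim: int = 26
    max_agc_iter: int = 60

    # DCF + training
    hidden_channels: int = 100
    q_cut: float = 0.5
    w_kl: float = 0.78
    w_ce: float = 0.71
    w_cont: float = 1.0
    w_ortho: float = 0.62
    w_diag: float | None = None
    lr_pretrain: float | None = None
    lr_train: float | None = None
    max_pretrain: int = 200
    max_train: int = 400
    p_update_every: int = 4
    min_cluster_frac: float = 0.01
    label_change_tol: float = 0.001
    ablation: str | None = None
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
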