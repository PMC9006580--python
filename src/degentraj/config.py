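"""Pipeline configuration: YAML-loadable, validated, with the study defaults."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class PipelineConfig:
    """All stage parameters with their standard defaults.

    ``input_dir`` points at a 10x-style triplet (with an optional
    ``cells.tsv`` carrying per-cell genotype); when it is None the bundled
    synthetic generator is run instead, with ``synthetic`` holding keyword
    overrides for the generator spec.
    """

    out_dir: str = "run"
    input_dir: str | None = None
    synthetic: dict = field(default_factory=dict)
    seed: int = 0

    mito_prefix: str = "mt-"
    min_cells_per_gene: int = 3
    min_features: int = 200
    max_features: int = 6000
    min_umi: int = 1000
    max_umi: int = 20000

    scale_factor: float = 10000.0
    n_hvg: int = 5000
    hvg_mean_lo: float = 0.1
    hvg_mean_hi: float = 8.0
    hvg_disp_min: float = 1.0
    clip_max: float = 10.0

    n_pcs: int = 50
    k_neighbors: int = 20
    snn_prune: float = 1.0 / 15.0
    resolution: float = 0.8

    marker_top_n: int = 10
    marker_min_auc: float = 0.8
    doublet_min_markers: int = 3
    doublet_type_corr: float = 0.8

    trajectory_markers: list = field(default_factory=lambda: ["Mk-rod-1"])
    trajectory_n_hvg: int = 3000
    trajectory_n_pcs: int = 12
    n_bins: int = 20
    min_bin_cells: int = 100
    assoc_knots: int = 6

    logfc_floor: float = 0.25
    min_pct: float = 0.1
    alpha: float = 0.05
    hemoglobin_prefixes: list = field(default_factory=lambda: ["Hba-", "Hbb-"])

    k_patterns: int = 4

    promoter_fasta: str | None = None
    motif_file: str | None = None
    promoter_upstream: int = 2000
    promoter_downstream: int = 500

    similarity_n_features: int = 5000
    similarity_min_cells: int = 50

    def validate(self) -> None:
        if self.n_pcs < 1 or self.k_neighbors < 1 or self.n_bins < 1:
            raise ValueError("n_pcs, k_neighbors and n_bins must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.min_features >= self.max_features or self.min_umi >= self.max_umi:
            raise ValueError("QC windows must have min < max")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def stage_seed(global_seed: int, stage: str) -> int:
    """Fan one global seed out per stage via a stable hash of the stage name."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16) % (2**31)


def params_hash(params: dict, upstream: str = "") -> str:
    blob = json.dumps({"params": params, "upstream": upstream}, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
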