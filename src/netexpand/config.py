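"""Declarative pipeline configuration with validation and stable hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, defaulting to the analysis constants."""

    # propagation
    damping: float = 0.85
    ppr_tol: float = 1e-12
    # module detection
    walktrap_steps: int = 8
    max_module_size: int = 300
    alpha: float = 0.05
    min_genes: int = 10
    min_seeds: int = 2
    # pleiotropy / trait similarity
    jaccard_threshold: float = 0.70
    linkage: str = "complete"
    height_clusters: float = 1.0
    height_subgroups: float = 0.7
    distance_use: str = "rank_score"
    distance_normalize: str | None = "max"
    min_subgroup_traits: int = 3
    # benchmarking
    n_perm: int = 1000
    benchmark_net_randomize: bool = False
    # locus prioritization
    n_null: int = 1000
    merge_window_bp: int = 200_000
    snp_window_bp: int = 10_000
    pct_hi: float = 90.0
    pct_competitor: float = 80.0
    ref_max_pct: float = 50.0
    l2g_min: float = 0.1
    snp_p_threshold: float = 5e-8
    prioritize_trait: str | None = None
    # synthetic scenario
    n_blocks: int = 5
    block_size: int = 60
    p_in: float = 0.2
    p_out: float = 0.01
    n_traits: int = 20
    seeds_per_trait: int = 8
    noise_frac: float = 0.2
    n_snps_per_gene: int = 5
    alpha_signal: float = 0.05
    # randomness
    rng_seed: int = 0
    # sources
    min_confidence_by_source: dict = field(default_factory=lambda: {"string": 0.75})

    def validate(self) -> None:
        checks = [
            (0 < self.damping < 1, "damping must lie in (0, 1)"),
            (self.ppr_tol > 0, "ppr_tol must be positive"),
            (self.walktrap_steps >= 1, "walktrap_steps must be >= 1"),
            (self.max_module_size >= 1, "max_module_size must be >= 1"),
            (0 < self.alpha < 1, "alpha must lie in (0, 1)"),
            (self.min_genes >= 1, "min_genes must be >= 1"),
            (self.min_seeds >= 1, "min_seeds must be >= 1"),
            (0 <= self.jaccard_threshold <= 1, "jaccard_threshold must lie in [0, 1]"),
            (self.linkage in ("complete", "average", "ward"), "unknown linkage"),
            (self.height_clusters >= 0, "height_clusters must be >= 0"),
            (self.height_subgroups >= 0, "height_subgroups must be >= 0"),
            (self.distance_use in ("rank_score", "score"), "unknown distance vector"),
            (self.n_perm >= 1, "n_perm must be >= 1"),
            (self.n_null >= 1, "n_null must be >= 1"),
            (self.merge_window_bp >= 0, "merge_window_bp must be >= 0"),
            (self.snp_window_bp >= 0, "snp_window_bp must be >= 0"),
            (0 <= self.pct_hi <= 100, "pct_hi must lie in [0, 100]"),
            (0 <= self.pct_competitor <= 100, "pct_competitor must lie in [0, 100]"),
            (0 <= self.ref_max_pct <= 100, "ref_max_pct must lie in [0, 100]"),
            (0 <= self.l2g_min <= 1, "l2g_min must lie in [0, 1]"),
            (0 < self.snp_p_threshold <= 1, "snp_p_threshold must lie in (0, 1]"),
            (0 <= self.p_out <= self.p_in <= 1, "need 0 <= p_out <= p_in <= 1"),
            (self.seeds_per_trait >= 2, "seeds_per_trait must be >= 2"),
            (0 <= self.noise_frac <= 1, "noise_frac must lie in [0, 1]"),
            (self.rng_seed >= 0, "rng_seed must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
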