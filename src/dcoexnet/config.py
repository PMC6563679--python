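"""Pipeline configuration with the analysis' default thresholds.

Defaults: DEG gate adjusted p < 0.05 with linear fold change outside
[0.9, 1.1]; co-expression gate |r| >= 0.80 at adjusted p <= 0.05;
differential ratio D >= 1; module filters (>= 10 genes, average connectivity
>= 10, clustering coefficient >= 0.5); MCODE vertex-weight percentage 0.2;
core-module cutoff 0.90; PCA variance threshold 0.85; k-means with k = 3 on
the first 3 components.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # differential expression
    deg_method: str = "moderated_t"
    deg_p: float = 0.05
    fc_up: float = 1.1
    fc_down: float = 0.9
    case_phenotype: str = "invasive"
    # co-expression network
    r_min: float = 0.80
    edge_p_max: float = 0.05
    d_min: float = 1.0
    module_network: str = "non-invasive"
    # MCODE + module filters
    vwp: float = 0.2
    haircut: bool = True
    min_core: int = 2
    min_module_nodes: int = 10
    min_avg_connectivity: float = 10.0
    min_module_cc: float = 0.5
    # core module
    core_r_min: float = 0.90
    core_modules: list[str] | None = None  # module ids to merge; None = all kept
    # subtype clustering / prognosis
    var_threshold: float = 0.85
    k_clusters: int = 3
    n_components: int = 3
    # enrichment
    enrich_alpha: float = 0.01
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.deg_p <= 1 or not 0 < self.edge_p_max <= 1:
            raise ValueError("p-value gates must be in (0, 1]")
        if not 0 < self.fc_down < 1 < self.fc_up:
            raise ValueError("fold-change gates must bracket 1")
        for r in (self.r_min, self.core_r_min):
            if not 0 < r <= 1:
                raise ValueError("correlation cutoffs must be in (0, 1]")
        if self.d_min < 0:
            raise ValueError("d_min must be non-negative")
        if not 0 <= self.vwp < 1:
            raise ValueError("vwp must be in [0, 1)")
        if not 0 < self.var_threshold <= 1:
            raise ValueError("var_threshold must be in (0, 1]")
        if self.k_clusters < 1 or self.n_components < 1:
            raise ValueError("k_clusters and n_components must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
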