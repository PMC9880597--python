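"""Pipeline configuration: the thresholds the analysis hinges on.

Defaults encode the filtering and testing rules used throughout: cells with
fewer than 2,000 UMIs or more than 15% mitochondrial UMIs are removed, the
top 2,000 variable genes feed dimensionality reduction, cluster labels are
inherited when an annotation covers at least 2% of a cluster, large groups
are subsampled to 2,000 cells before differential expression, and a gene is
called differential at fold change > 2 with BH-adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    min_umis: int = 2000
    max_mito_frac: float = 0.15
    n_hvg: int = 2000
    n_pcs: int = 20
    knn_k: int = 15
    cluster_resolution: float = 1.0
    anchor_k: int = 10
    min_label_frac: float = 0.02
    de_subsample: int = 2000
    fc_threshold: float = 2.0
    alpha: float = 0.05
    cpt_scale: float = 1000.0
    n_permutations: int = 1000
    rng_seed: int = 0
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        for name in (
            "min_umis", "n_hvg", "n_pcs", "knn_k", "cluster_resolution",
            "anchor_k", "de_subsample", "fc_threshold", "cpt_scale",
            "n_permutations",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("max_mito_frac", "min_label_frac", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
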