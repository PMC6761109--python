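"""Run configuration: one validated namespace of tunable parameters.

Every operation's tunables live here with their defaults so a CLI run can be
replayed from its logged, resolved configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

logger = logging.getLogger("psionic")


@dataclass
class RunConfig:
    # feature construction
    merge_overlap_frac: float = 0.75          # fraction of the shorter interval
    merge_mode: str = "shorter"               # or "reciprocal"
    assign_flank: int = 100_000               # bp either side of the transcription unit
    promoter_window: int = 2_000              # bp around the TSS for promoter-only mode
    expressed_threshold: float = 0.0          # "expressed" = value > threshold
    expressed_min_frac: float = 0.5
    jaccard_threshold: float = 0.5
    standardize_features: bool = True         # z-score X columns before regression

    # expression normalization
    pseudocount: float = 1.0
    log_input: bool = False

    # model
    n_latent: int = 7                         # K
    mu: float = 1e-3                          # L1 penalty on S
    lam: float = 1e-3                         # Frobenius penalty on L
    lam_ridge: float = 0.01                   # STL ridge penalty
    tol: float = 1e-6
    max_iter: int = 200
    init: str = "stl"                         # or "random"

    # evaluation
    n_folds: int = 10
    top_k_tfs: int = 20
    n_permutations: int = 10_000

    # enrichment
    topk_peaks: int = 5000
    min_members: int = 10
    enrich_pseudocount: float = 0.5
    ks_background: str = "all"                # or "rest"

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.merge_overlap_frac <= 1:
            raise ValueError("merge_overlap_frac must be in (0, 1]")
        if self.merge_mode not in ("shorter", "reciprocal"):
            raise ValueError("merge_mode must be 'shorter' or 'reciprocal'")
        if self.assign_flank < 0 or self.promoter_window < 0:
            raise ValueError("window sizes must be nonnegative")
        if not 0 <= self.expressed_min_frac <= 1:
            raise ValueError("expressed_min_frac must be in [0, 1]")
        if not 0 <= self.jaccard_threshold <= 1:
            raise ValueError("jaccard_threshold must be in [0, 1]")
        if self.n_latent < 1:
            raise ValueError("n_latent (K) must be >= 1")
        if self.mu < 0 or self.lam < 0 or self.lam_ridge < 0:
            raise ValueError("penalties must be nonnegative")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter >= 1 and tol > 0 required")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.ks_background not in ("all", "rest"):
            raise ValueError("ks_background must be 'all' or 'rest'")

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: configuration must be a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def log_resolved(self) -> None:
        """Log the fully resolved configuration so the run is replayable."""
        logger.info("resolved configuration: %s", json.dumps(self.to_dict(), sort_keys=True))
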