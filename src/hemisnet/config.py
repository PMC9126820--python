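"""Analysis configuration, mirrored field-for-field by the YAML config."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml


@dataclass
class AnalysisConfig:
    """Tunable parameters of the asymmetry analysis.

    Defaults follow the main analysis: sparsity 0.4, 10,000 label-swap
    permutations, 100 degree-preserving null networks per hemisphere for
    the small-world normalization, Bonferroni 0.05/3 at the hemisphere
    tier and BH-FDR with threshold 0.05/4 at the node tier (four node
    metrics are tested).
    """

    sparsity: float = 0.4
    sparsity_range: tuple[float, float] = (0.25, 0.50)
    sparsity_step: float = 0.01
    n_permutations: int = 10_000
    n_null_networks: int = 100
    rng_seed: int = 0
    alpha_hemisphere: float = 0.05 / 3
    alpha_node: float = 0.05 / 4
    alpha_edge: float = 0.05
    nonlinear_age: bool = False
    global_thickness_covariate: bool = False
    pooled_reference: bool = False  # control reference pooled across datasets
    within_dataset_permutation: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.sparsity <= 1:
            raise ValueError(f"sparsity must be in (0, 1], got {self.sparsity}")
        lo, hi = self.sparsity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"sparsity_range must lie within (0, 1], got {self.sparsity_range}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.n_null_networks < 1:
            raise ValueError("n_null_networks must be >= 1")

    @property
    def sparsity_grid(self) -> np.ndarray:
        """Thresholds of the sensitivity sweep (26 values at defaults)."""
        lo, hi = self.sparsity_range
        n = int(round((hi - lo) / self.sparsity_step)) + 1
        return np.round(np.linspace(lo, hi, n), 10)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sparsity_range" in raw:
            raw["sparsity_range"] = tuple(raw["sparsity_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["sparsity_range"] = list(data["sparsity_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
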