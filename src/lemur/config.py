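"""Run configuration for the differential-expression pipeline."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field


@dataclass
class RunConfig:
    """All pipeline knobs with their defaults.

    Defaults: 30 latent dimensions, 50% test fraction, 100 random
    directions, z-score neighborhood selection, at least 10 cells per
    neighborhood, normed-sum size factors, negative-binomial LRT pseudobulk
    test, nominal FDR 10%.
    """

    n_embedding: int = 30
    test_fraction: float = 0.5
    n_directions: int = 100
    min_cells: int = 10
    selection_procedure: str = "zscore"  # or "contrast"
    size_factor_method: str = "normed_sum"
    test_method: str = "nb_lrt"  # or "lm"
    nominal_fdr: float = 0.1
    lambda_align: float | None = None
    align_n_clusters: int = 0  # derive k-means matching sets for alignment; 0 disables
    offset_trim: float = 0.3  # fraction of highest-|delta| genes excluded from size-factor totals
    pseudo_count: float = 1.0
    seed: int = 0
    test_on_train: bool = False  # diagnostic variant: reuse training cells for testing
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.test_fraction <= 0.95:
            raise ValueError("test_fraction must be in [0, 0.95]")
        if self.n_embedding < 1:
            raise ValueError("n_embedding must be >= 1")
        if self.selection_procedure not in {"zscore", "contrast"}:
            raise ValueError("selection_procedure must be 'zscore' or 'contrast'")
        if self.test_method not in {"nb_lrt", "lm"}:
            raise ValueError("test_method must be 'nb_lrt' or 'lm'")
        if self.seed is None:
            raise ValueError("seed must be set explicitly")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load from JSON/YAML; keyword overrides (for example CLI flags) win."""
        text = open(path).read()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
        data = {**data, **{k: v for k, v in overrides.items() if v is not None}}
        data.setdefault("provenance", {})
        data["provenance"] = {
            "config_file": str(path),
            "overrides": sorted(k for k, v in overrides.items() if v is not None),
        }
        return cls(**data)
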