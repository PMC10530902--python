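"""Pipeline configuration: defaults, validation, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs.

    The scoring defaults mirror the original study scale: 50 holdout
    models, 10 label shuffles for the background, EP cutoffs
    0.001/0.005/0.01, 80% training fraction.
    """

    expression: str = ""
    labels: str = ""
    survival: str | None = None
    gene_sets: str | None = None
    network: str | None = None
    gene_universe: str | None = None
    gene_map: str | None = None
    sample_map: str | None = None

    out_dir: str = "results"
    n_models: int = 50
    n_shuffles: int = 10
    ep_cutoffs: list = field(default_factory=lambda: [0.001, 0.005, 0.01])
    train_fraction: float = 0.8
    seed: int = 0
    backend: str = "xgboost"
    importance_type: str = "total_gain"
    backend_params: dict = field(default_factory=dict)
    log_base: float = 2.0
    pseudocount: float = 1.0
    alpha_ttest: float = 0.1
    survival_cohort: str | None = "M1"
    skip_preprocess: bool = False

    def validate(self) -> "PipelineConfig":
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must be in (0,1), got {self.train_fraction}")
        cuts = list(self.ep_cutoffs)
        if any(c <= 0 or c > 1 for c in cuts) or any(
            b <= a for a, b in zip(cuts, cuts[1:])
        ):
            raise ValueError(f"ep_cutoffs must be strictly increasing in (0,1], got {cuts}")
        if self.n_models < 1 or self.n_shuffles < 1:
            raise ValueError("n_models and n_shuffles must be >= 1")
        if not self.expression or not self.labels:
            raise ValueError("expression and labels paths are required")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
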