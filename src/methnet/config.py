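"""Pipeline configuration: YAML round-trip, validation, stage seeds."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .containers import ValidationError


@dataclass
class PipelineConfig:
    """Parameters of a full pipeline run.

    Paths are optional: stages that find them empty fall back to the
    artifacts written by earlier stages in the output directory.
    """

    # input paths (empty string = use upstream stage artifacts)
    beta_path: str = ""
    phenotype_path: str = ""
    annotation_path: str = ""
    gene_sets_path: str = ""
    cell_reference_path: str = ""
    smoking_effects_path: str = ""

    # preprocessing
    epsilon: float = 1e-6
    bloodbrain_alpha: float = 0.05
    quantile_normalize: bool = False

    # network
    powers: list[int] = field(default_factory=lambda: list(range(1, 21)))
    r2_min: float = 0.90
    min_module_size: int = 10
    cut_fraction: float = 0.95
    cut_height: float | None = None
    signed_network: bool = False

    # inference
    fdr_q: float = 0.10
    nominal_alpha: float = 0.05
    n_draws: int = 10_000
    contrast: str = "range"
    enrichment_min_size: int = 25
    enrichment_max_size: int = 1000

    # simulation (used by the simulate stage)
    n_samples: int = 97
    n_probes: int = 2000

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_q < 1.0:
            raise ValidationError("fdr_q must lie in (0, 1)")
        if not 0.0 < self.nominal_alpha < 1.0:
            raise ValidationError("nominal_alpha must lie in (0, 1)")
        if not 0.0 < self.epsilon < 0.5:
            raise ValidationError("epsilon must lie in (0, 0.5)")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed, so
        stages are independently reproducible."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]
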