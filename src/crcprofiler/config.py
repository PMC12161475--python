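"""Pipeline configuration.

Every threshold the pipeline applies is collected here so that a single YAML
file fully determines a run: the evidence-score cutoff (0.5), the MANTIS
MSI/MSS boundaries (0.6/0.4), the variant confidence minimum (8/10), the
adjusted-p and minimum-mutated-sample rules for cohort comparison (0.1 / 4),
the |NES| >= 2 significance convention, the exome capture size used as the
TMB denominator, and the high-TMB boundary for the immune-evasion basket.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class GridConfig:
    """Tumor-cell-content / ploidy search grid."""

    tcc_min: float = 0.05
    tcc_max: float = 1.0
    tcc_step: float = 0.01
    ploidy_min: float = 1.0
    ploidy_max: float = 6.5
    ploidy_step: float = 0.05
    dh_term: bool = False  # add an explicit |dh_obs - dh_state| distance term


@dataclass
class PipelineConfig:
    """All tunable thresholds and run-level settings, YAML round-trippable."""

    seed: int = 0
    # variant scoring
    min_confidence: int = 8
    svracas_cutoff: float = 0.5
    evidence_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    expr_min_count: int = 10
    expr_min_samples: int = 5
    # purity / ploidy
    grid: GridConfig = field(default_factory=GridConfig)
    min_het_snps: int = 20
    het_af_low: float = 0.3
    het_af_high: float = 0.7
    balanced_low: float = 0.45
    balanced_high: float = 0.55
    # cohort characterization
    mantis_msi: float = 0.6
    mantis_mss: float = 0.4
    capture_mb: float = 35.0
    p_adj_max: float = 0.1
    min_mutated: int = 4
    # activity inference
    n_perm: int = 1000
    min_regulon_size: int = 5
    ssgsea_alpha: float = 0.75
    ssgsea_min_size: int = 10
    nes_threshold: float = 2.0
    # stratification
    var_threshold: float = 0.95
    max_clusters: int = 10
    consolidate: bool = True
    tmb_high: float = 10.0

    def validate(self) -> None:
        if not (0 <= self.svracas_cutoff <= 1):
            raise ValueError("svracas_cutoff must be in [0, 1]")
        if not (1 <= self.min_confidence <= 10):
            raise ValueError("min_confidence must be in [1, 10]")
        if self.capture_mb <= 0:
            raise ValueError("capture_mb must be positive")
        if self.mantis_mss > self.mantis_msi:
            raise ValueError("mantis_mss boundary must not exceed mantis_msi")
        if any(w < 0 for w in self.evidence_weights):
            raise ValueError("evidence weights must be nonnegative")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["evidence_weights"] = list(self.evidence_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "grid" in d and isinstance(d["grid"], dict):
            d["grid"] = GridConfig(**d["grid"])
        if "evidence_weights" in d:
            d["evidence_weights"] = tuple(d["evidence_weights"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Short stable digest identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
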