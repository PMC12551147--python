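"""Campaign configuration: schema-checked YAML/JSON with filled defaults.

Configs are strict (unknown keys rejected) and validation reports every
violation at once.  The validated object converts to the runtime dataclasses
(:class:`teploop.ml.ModelConfig`, :class:`teploop.design.SelectionPolicy`,
:class:`teploop.synthetic.LandscapeSpec`).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .design import SelectionPolicy
from .ml import ModelConfig
from .synthetic import LandscapeSpec


class ConfigError(ValueError):
    """Aggregated, human-readable configuration errors."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSettings(_Strict):
    algorithm: str = "random_forest"
    n_trees: int = Field(default=1000, ge=1)
    n_folds: int = Field(default=5, ge=2)
    seed: int = 0


class PolicySettings(_Strict):
    pool_size: int = Field(default=5000, ge=1)
    batch_size: int = Field(default=50, ge=0)
    n_top: int = Field(default=25, ge=0)
    n_cluster_reps: int = Field(default=15, ge=0)
    n_random: int = Field(default=10, ge=0)
    k_clusters: int = Field(default=15, ge=1)

    @model_validator(mode="after")
    def _strata(self):
        if self.n_top + self.n_cluster_reps + self.n_random != self.batch_size:
            raise ValueError("n_top + n_cluster_reps + n_random must equal batch_size")
        return self


class LandscapeSettings(_Strict):
    sparsity: float = Field(default=0.05, gt=0, le=1)
    target_score_sd: float = Field(default=0.4, gt=0)
    noise_sd: float = Field(default=0.1, ge=0)
    replicates: int = Field(default=3, ge=1)
    transform: str = "exp"
    skew_alpha: float = 1.0
    reference: str = "SKIK"
    seed: int = 2024


class PathsSettings(_Strict):
    scales_dir: Optional[str] = None
    codon_table: Optional[str] = None
    activity_file: Optional[str] = None


class CampaignConfig(_Strict):
    """Full campaign configuration with documented defaults."""

    model: ModelSettings = ModelSettings()
    policy: PolicySettings = PolicySettings()
    landscape: LandscapeSettings = LandscapeSettings()
    paths: PathsSettings = PathsSettings()
    n_rounds: int = Field(default=3, ge=1)
    seed: int = 0
    out_dir: Optional[str] = None

    def to_model_config(self) -> ModelConfig:
        m = self.model
        return ModelConfig(
            algorithm=m.algorithm, n_trees=m.n_trees, n_folds=m.n_folds, seed=m.seed
        )

    def to_policy(self) -> SelectionPolicy:
        p = self.policy
        return SelectionPolicy(
            pool_size=p.pool_size,
            batch_size=p.batch_size,
            n_top=p.n_top,
            n_cluster_reps=p.n_cluster_reps,
            n_random=p.n_random,
            k_clusters=p.k_clusters,
            seed=self.seed,
        )

    def to_landscape_spec(self) -> LandscapeSpec:
        s = self.landscape
        return LandscapeSpec(
            sparsity=s.sparsity,
            target_score_sd=s.target_score_sd,
            noise_sd=s.noise_sd,
            replicates=s.replicates,
            transform=s.transform,
            skew_alpha=s.skew_alpha,
            reference=s.reference,
            seed=s.seed,
        )

    def content_hash(self) -> str:
        """Stable hash recorded in every output artifact for provenance."""
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def validate_config(path) -> CampaignConfig:
    """Load and validate a YAML/JSON config file, listing all violations."""
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        config = CampaignConfig.model_validate(data)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(loc) for loc in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(
            f"{path}: {len(lines)} configuration error(s):\n" + "\n".join(lines)
        ) from None
    for label, p in (
        ("paths.scales_dir", config.paths.scales_dir),
        ("paths.codon_table", config.paths.codon_table),
        ("paths.activity_file", config.paths.activity_file),
    ):
        if p is not None and not Path(p).exists():
            raise ConfigError(f"{path}: {label} does not exist: {p}")
    return config


def emit_config(config: CampaignConfig, path) -> None:
    """Write a config back to YAML; validate(emit(c)) round-trips."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
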