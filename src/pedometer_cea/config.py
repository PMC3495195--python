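"""Pipeline configuration: schema, validation, and hashing.

A single structured YAML file configures every stage; command-line flags
override individual fields. Defaults reproduce the deterministic base case.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

__all__ = ["PipelineConfig", "load_config", "validate_config", "config_hash"]


class CascadeSection(BaseModel):
    base_population: float = Field(7_270_000.0, ge=0)
    f_gp: float = Field(0.375, ge=0, le=1)
    f_squash: float = Field(0.83, ge=0, le=1)
    f_target: float = Field(0.441, ge=0, le=1)
    f_accept: float = Field(0.50, ge=0, le=1)
    f_followup: float = Field(0.50, ge=0, le=1)


class CostSection(BaseModel):
    c_approach: float = Field(0.66, ge=0)
    c_scoring: float = Field(6.66, ge=0)
    c_counseling: float = Field(22.20, ge=0)
    c_pedometer: float = Field(19.95, ge=0)
    c_followup: float = Field(19.80, ge=0)


class EffectSection(BaseModel):
    steps_effect_1yr: float = Field(2491.0, gt=0)
    step_pace: float = Field(106.0, gt=0)
    maintenance_fraction: float = Field(0.25, gt=0, le=1)


class SynthSection(BaseModel):
    n_survey: int = Field(10_000, ge=1)
    walking_shape: float = Field(1.2, gt=0)
    walking_scale: float = Field(30.0, gt=0)
    activity_slope: float = Field(0.2, gt=0)
    target_distribution: tuple[float, float, float] = (0.17, 0.27, 0.56)
    calibration_tolerance: float = Field(0.02, gt=0)
    null_epi: bool = False

    @field_validator("target_distribution")
    @classmethod
    def _sums_to_one(cls, v):
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("target_distribution must sum to 1")
        return v


class DiscountSection(BaseModel):
    effects_rate: float = Field(0.015, ge=0)
    costs_rate: float = Field(0.04, ge=0)


class PSASection(BaseModel):
    n_runs: int = Field(1000, ge=1)
    lambda_max: float = Field(50_000.0, gt=0)
    lambda_step: float = Field(1_000.0, gt=0)
    incidence_exposure: float = Field(1e5, gt=0)
    prevalence_n: int = Field(10_000, ge=1)
    mortality_exposure: float = Field(1e4, gt=0)
    couple_epi: bool = True


class PipelineConfig(BaseModel):
    """Validated configuration of the full analysis pipeline."""

    cascade: CascadeSection = Field(default_factory=CascadeSection)
    costs: CostSection = Field(default_factory=CostSection)
    effect: EffectSection = Field(default_factory=EffectSection)
    synth: SynthSection = Field(default_factory=SynthSection)
    discount: DiscountSection = Field(default_factory=DiscountSection)
    psa: PSASection = Field(default_factory=PSASection)
    age_split: int = Field(55, ge=21, le=64)
    epi_csv_dir: str | None = None  # load epidemiology from CSVs instead of generating


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config file (defaults when ``path`` is None), applying overrides."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    for key, value in (overrides or {}).items():
        section, _, leaf = key.partition(".")
        if leaf:
            data.setdefault(section, {})[leaf] = value
        else:
            data[section] = value
    return PipelineConfig.model_validate(data)


def validate_config(data: dict | PipelineConfig) -> tuple[bool, list[str]]:
    """Validate a config, reporting *all* violations, not just the first.

    Returns ``(ok, messages)``.
    """
    messages: list[str] = []
    if isinstance(data, PipelineConfig):
        cfg = data
    else:
        try:
            cfg = PipelineConfig.model_validate(data)
        except ValidationError as err:
            for e in err.errors():
                loc = ".".join(str(p) for p in e["loc"])
                messages.append(f"{loc}: {e['msg']}")
            return False, messages
    if cfg.epi_csv_dir is not None and not Path(cfg.epi_csv_dir).is_dir():
        messages.append(f"epi_csv_dir: directory not found: {cfg.epi_csv_dir}")
    return not messages, messages


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the configuration, stamped into every output."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
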