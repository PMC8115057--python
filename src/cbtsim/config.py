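"""YAML run configuration: schema, validation, and conversion to model objects.

A run configuration names one experiment (``single_trial``, ``sweep``,
``exposure``, or ``generalization``) and carries the clinical parameters,
engine options, and learning options.  Validation is strict: unknown keys and
out-of-range values are rejected with field-level messages.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .engine import EXPOSURE_PRIOR_EPS
from .learning import A_FLOOR_DEFAULT, CAB_LEAK_DEFAULT
from .model import CBTParams
from .protocols import (
    BASE_SCALE_D_DEFAULT,
    BASE_SCALE_DEFAULT,
    DEFAULT_EXPOSURE_LENGTHS,
    ETA_A_DEFAULT,
    ETA_D_DEFAULT,
    GAMMA_DEFAULT,
    ExperimentConfig,
)

__all__ = ["RunConfig", "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParamsSection(_Strict):
    """Clinical parameters of the avoidance model."""

    danger: float = Field(0.9, ge=0.0, le=1.0)
    cab_i: float = Field(0.9, ge=0.0, le=1.0)
    preference_harm: float = -12.0
    preference_negative: float = -1.0
    preference_high_arousal: float = -1.0
    arousal_dialect: Literal["belief_modulated", "literal_text"] = "belief_modulated"
    pre_choice_outcome: Literal["neutral", "positive_affect"] = "neutral"


class EngineSection(_Strict):
    gamma: float = Field(GAMMA_DEFAULT, ge=0.0)
    alpha_action: Optional[float] = None
    include_novelty: Optional[bool] = None
    exposure_mode: Literal["habit_prior", "response_prevention"] = "habit_prior"
    exposure_eps: float = Field(EXPOSURE_PRIOR_EPS, gt=0.0, lt=1.0)


class LearningSection(_Strict):
    enabled: bool = True
    base_scale: float = Field(BASE_SCALE_DEFAULT, gt=0.0)
    base_scale_d: float = Field(BASE_SCALE_D_DEFAULT, gt=0.0)
    a_floor: float = Field(A_FLOOR_DEFAULT, ge=0.0)
    cab_leak: float = Field(CAB_LEAK_DEFAULT, ge=0.0, le=1.0)
    eta_a: float = Field(ETA_A_DEFAULT, ge=0.0)
    eta_d: float = Field(ETA_D_DEFAULT, ge=0.0)


class ProtocolSection(_Strict):
    exposure_lengths: list[int] = Field(default_factory=lambda: list(DEFAULT_EXPOSURE_LENGTHS))
    n_probe_reps: int = Field(50, gt=0)
    n_sweep_trials: int = Field(100, gt=0)
    approach_criterion: float = Field(0.95, gt=0.0, le=1.0)
    danger_grid: list[float] = Field(default_factory=lambda: [1.0, 0.9, 0.75, 0.5, 0.25, 0.1, 0.0])
    cab_grid: list[float] = Field(default_factory=lambda: [0.1, 0.5, 0.9])
    reinstated_danger: float = Field(0.9, ge=0.0, le=1.0)


class RunConfig(_Strict):
    """Top-level run configuration for the command-line interface."""

    experiment: Literal["single_trial", "sweep", "exposure", "generalization"]
    seed: int = Field(0, ge=0)
    output_dir: str = "results"
    params: ParamsSection = Field(default_factory=ParamsSection)
    engine: EngineSection = Field(default_factory=EngineSection)
    learning: LearningSection = Field(default_factory=LearningSection)
    protocol: ProtocolSection = Field(default_factory=ProtocolSection)

    def cbt_params(self) -> CBTParams:
        p = self.params
        return CBTParams(
            danger=p.danger,
            cab_i=p.cab_i,
            preference_harm=p.preference_harm,
            preference_negative=p.preference_negative,
            preference_high_arousal=p.preference_high_arousal,
            arousal_dialect=p.arousal_dialect,
            pre_choice_outcome=p.pre_choice_outcome,
        )

    def experiment_config(self) -> ExperimentConfig:
        return ExperimentConfig(
            danger_prior=self.params.danger,
            cab_i=self.params.cab_i,
            exposure_lengths=tuple(self.protocol.exposure_lengths),
            n_probe_reps=self.protocol.n_probe_reps,
            n_sweep_trials=self.protocol.n_sweep_trials,
            approach_criterion=self.protocol.approach_criterion,
            seed=self.seed,
            learning=self.learning.enabled,
            gamma=self.engine.gamma,
            alpha_action=self.engine.alpha_action,
            arousal_dialect=self.params.arousal_dialect,
            pre_choice_outcome=self.params.pre_choice_outcome,
            exposure_mode=self.engine.exposure_mode,
            exposure_eps=self.engine.exposure_eps,
            include_novelty=self.engine.include_novelty,
            base_scale=self.learning.base_scale,
            base_scale_d=self.learning.base_scale_d,
            a_floor=self.learning.a_floor,
            cab_leak=self.learning.cab_leak,
            eta_a=self.learning.eta_a,
            eta_d=self.learning.eta_d,
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return RunConfig.model_validate(raw)


def config_hash(config: RunConfig) -> str:
    """Stable hash of the full (validated) configuration."""
    canonical = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
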