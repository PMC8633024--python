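"""Run configuration: a fully serializable description of one simulation.

A simulation run is a pure function of its :class:`RunConfig`; the YAML
round trip preserves every generative parameter.  Nested blocks use
plain string keys ("computer"/"robot", condition names) so configs stay
hand-editable.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .agent import AgentParams
from .design import Condition, Group
from .participant import InfluencePolicyParams, ObserverParams, RatingModel

__all__ = ["RunConfig", "load_config", "save_config"]


class AgentConfig(BaseModel):
    estimate_sd: float = 1.52
    resample_threshold: float = 0.5
    resample_prob: float = 0.5

    def to_params(self) -> AgentParams:
        return AgentParams(
            estimate_sd=self.estimate_sd,
            resample_threshold=self.resample_threshold,
            resample_prob=self.resample_prob,
        )


class ObserverConfig(BaseModel):
    weber_fraction: float = 0.30
    prior_sd: float = 3.8
    motor_sd: float = 1.7
    prior_update_rate: float = 0.12
    # Multiplicative weber_fraction modifiers per group and reciprocal
    # condition (phenomenological learning).
    weber_modifiers: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "computer": {"susceptible": 0.80, "unsusceptible": 0.80},
            "robot": {"susceptible": 1.30, "unsusceptible": 1.12},
        }
    )

    def to_params(self) -> ObserverParams:
        return ObserverParams(
            weber_fraction=self.weber_fraction,
            prior_sd=self.prior_sd,
            motor_sd=self.motor_sd,
            prior_update_rate=self.prior_update_rate,
        )

    def modifier(self, group: Group, condition: Condition | None) -> float:
        if condition is None:
            return 1.0
        return self.weber_modifiers.get(group.value, {}).get(condition.value, 1.0)


class PolicyConfig(BaseModel):
    baseline_influence: dict[str, float] = Field(
        default_factory=lambda: {"computer": -0.80, "robot": -0.26}
    )
    distance_slope: float = -1.9
    condition_shift: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "computer": {"susceptible": 0.17, "unsusceptible": 0.22},
            "robot": {"susceptible": 0.0, "unsusceptible": 0.05},
        }
    )
    final_block_shift: dict[str, float] = Field(
        default_factory=lambda: {"computer": -0.08, "robot": -0.17}
    )
    policy_noise_sd: float = 0.9

    def to_params(self) -> InfluencePolicyParams:
        return InfluencePolicyParams(
            baseline_influence={Group(k): v for k, v in self.baseline_influence.items()},
            distance_slope=self.distance_slope,
            condition_shift={
                Group(g): {Condition(c): v for c, v in shifts.items()}
                for g, shifts in self.condition_shift.items()
            },
            final_block_shift={Group(k): v for k, v in self.final_block_shift.items()},
            policy_noise_sd=self.policy_noise_sd,
        )


class RatingConfig(BaseModel):
    self_rating_base: float = 6.3
    other_rating_base: float = 6.0
    susceptibility_penalty: float = 2.4
    rating_noise_sd: float = 0.6
    between_subject_sd: float = 1.0

    def to_params(self) -> RatingModel:
        return RatingModel(
            self_rating_base=self.self_rating_base,
            other_rating_base=self.other_rating_base,
            susceptibility_penalty=self.susceptibility_penalty,
            rating_noise_sd=self.rating_noise_sd,
            between_subject_sd=self.between_subject_sd,
        )


class RunConfig(BaseModel):
    n_per_group: int = 25
    seed: int = 0
    agent: AgentConfig = Field(default_factory=AgentConfig)
    observer: ObserverConfig = Field(default_factory=ObserverConfig)
    policy: PolicyConfig = Field(default_factory=PolicyConfig)
    ratings: RatingConfig = Field(default_factory=RatingConfig)
    out_dir: str = "results"
    run_models: bool = True
    run_nonparametric: bool = True

    @field_validator("n_per_group")
    @classmethod
    def _check_n(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_per_group must be >= 1")
        return v


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(payload)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
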