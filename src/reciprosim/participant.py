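"""Generative model of the synthetic human participant.

Perception follows a central-tendency observer: sensory noise grows
proportionally with stimulus length (scalar variability), and the
estimate is a precision-weighted blend of the noisy percept with a
running prior over the stimulus history.  Because long stimuli are
noisier they are pulled toward the prior more strongly, which yields
flattened response slopes and net underestimation of the 12 cm design
mean — the three signatures the analysis pipeline expects.

Final decisions use a logit-linear influence policy: a group-specific
baseline, a negative slope on the normalized distance between the two
estimates, additive condition/final-block shifts, and logit-scale noise,
squashed back to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .design import Condition, Group
from .stimuli import SCREEN_WIDTH_CM

__all__ = [
    "ObserverParams",
    "Observer",
    "InfluencePolicyParams",
    "RatingModel",
    "perceive_and_estimate",
    "decide_influence",
    "participant_final_decision",
    "emit_ratings",
]


@dataclass
class ObserverParams:
    """Parameters of the perceptual estimate generator.

    ``weber_fraction`` scales sensory noise with stimulus length
    (sigma_s = weber_fraction * s).  ``prior_sd`` sets how strongly the
    running prior attracts the percept; ``prior_update_rate`` is the
    per-trial step of the running prior mean toward the current percept.
    """

    weber_fraction: float = 0.30
    prior_sd: float = 3.8
    motor_sd: float = 1.7
    prior_update_rate: float = 0.12

    def __post_init__(self) -> None:
        if not 0 < self.weber_fraction < 1:
            raise ValueError("weber_fraction must be in (0, 1)")
        if self.prior_sd <= 0 or self.motor_sd < 0:
            raise ValueError("prior_sd must be > 0 and motor_sd >= 0")
        if not 0 <= self.prior_update_rate <= 1:
            raise ValueError("prior_update_rate must be in [0, 1]")


@dataclass
class Observer:
    """Stateful observer: parameters plus the running prior mean.

    The prior mean is initialized at the first percept and thereafter
    updated toward each new percept by ``prior_update_rate``.
    """

    params: ObserverParams
    prior_mean: float | None = None

    def reset(self) -> None:
        self.prior_mean = None


def perceive_and_estimate(s: float, observer: Observer, rng: np.random.Generator) -> float:
    """Generate one perceptual estimate of a stimulus of length ``s`` cm."""
    if s <= 0:
        raise ValueError("stimulus length must be positive")
    p = observer.params
    sigma_s = p.weber_fraction * s
    percept = rng.normal(s, sigma_s)
    if observer.prior_mean is None:
        observer.prior_mean = percept
    lam = sigma_s**2 / (sigma_s**2 + p.prior_sd**2)
    estimate = lam * observer.prior_mean + (1.0 - lam) * percept
    if p.motor_sd > 0:
        estimate += rng.normal(0.0, p.motor_sd)
    observer.prior_mean += p.prior_update_rate * (percept - observer.prior_mean)
    return float(np.clip(estimate, 0.1, SCREEN_WIDTH_CM))


def _default_condition_shifts() -> dict[Group, dict[Condition, float]]:
    # Computer partners elicit a positive influence shift in both
    # reciprocal conditions; robot partners elicit none.
    return {
        Group.COMPUTER: {
            Condition.SUSCEPTIBLE: 0.17,
            Condition.UNSUSCEPTIBLE: 0.22,
        },
        Group.ROBOT: {
            Condition.SUSCEPTIBLE: 0.0,
            Condition.UNSUSCEPTIBLE: 0.05,
        },
    }


def _default_weber_modifiers() -> dict[Group, dict[Condition, float]]:
    # Phenomenological learning: computer-group error drops in both
    # reciprocal conditions; robot-group error rises when the partner is
    # susceptible.
    return {
        Group.COMPUTER: {
            Condition.SUSCEPTIBLE: 0.80,
            Condition.UNSUSCEPTIBLE: 0.80,
        },
        Group.ROBOT: {
            Condition.SUSCEPTIBLE: 1.30,
            Condition.UNSUSCEPTIBLE: 1.12,
        },
    }


@dataclass
class InfluencePolicyParams:
    """Logit-linear policy for the participant's final-decision influence."""

    baseline_influence: dict[Group, float] = field(
        default_factory=lambda: {Group.COMPUTER: -0.80, Group.ROBOT: -0.26}
    )
    distance_slope: float = -1.9
    condition_shift: dict[Group, dict[Condition, float]] = field(
        default_factory=_default_condition_shifts
    )
    final_block_shift: dict[Group, float] = field(
        default_factory=lambda: {Group.COMPUTER: -0.08, Group.ROBOT: -0.17}
    )
    policy_noise_sd: float = 0.9


def decide_influence(
    normalized_distance: float,
    group: Group,
    condition: Condition,
    is_final_block: bool,
    policy: InfluencePolicyParams,
    rng: np.random.Generator,
) -> float:
    """Draw the participant's influence for one decision turn."""
    if normalized_distance < 0:
        raise ValueError("normalized_distance must be >= 0")
    logit = policy.baseline_influence[group]
    logit += policy.distance_slope * normalized_distance
    logit += policy.condition_shift.get(group, {}).get(condition, 0.0)
    if is_final_block:
        logit += policy.final_block_shift[group]
    if policy.policy_noise_sd > 0:
        logit += rng.normal(0.0, policy.policy_noise_sd)
    return float(np.clip(expit(logit), 0.0, 1.0))


def participant_final_decision(own: float, other: float, i: float) -> float:
    """Place the final decision between the two estimates: own + i*(other-own)."""
    if not 0.0 <= i <= 1.0:
        raise ValueError(f"influence must be in [0, 1], got {i}")
    return own + i * (other - own)


@dataclass
class RatingModel:
    """Generator of 1-10 performance ratings at the scheduled pauses.

    The rating gap (self minus other) widens as the partner shows more
    influence: susceptibility is read as incompetence.
    """

    self_rating_base: float = 6.3
    other_rating_base: float = 6.0
    susceptibility_penalty: float = 2.4
    rating_noise_sd: float = 0.6
    between_subject_sd: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.self_rating_base, self.other_rating_base):
            if not 1 <= v <= 10:
                raise ValueError("rating bases must lie in [1, 10]")


def emit_ratings(
    observed_partner_influence: float,
    model: RatingModel,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Return (self_rating, other_rating), each clamped to [1, 10]."""
    if not 0.0 <= observed_partner_influence <= 1.0:
        raise ValueError("observed_partner_influence must be in [0, 1]")
    self_r = model.self_rating_base
    other_r = model.other_rating_base - model.susceptibility_penalty * observed_partner_influence
    if rng is not None and model.rating_noise_sd > 0:
        self_r += rng.normal(0.0, model.rating_noise_sd)
        other_r += rng.normal(0.0, model.rating_noise_sd)
    return (
        float(np.clip(self_r, 1.0, 10.0)),
        float(np.clip(other_r, 1.0, 10.0)),
    )
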