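"""Stochastic behavior of the partner agent (computer/robot).

The agent's perceptual estimate is an unbiased Gaussian draw around the
true length; a resampling rule keeps it from landing on top of the
participant's response too often.  In observation turns of the
reciprocal task its final decision shifts toward the participant's
estimate by a trial-level "influence" value drawn from a
condition-specific mixture of uniform interval distributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .design import Condition
from .stimuli import SCREEN_WIDTH_CM

__all__ = [
    "AgentParams",
    "AgentEstimate",
    "InfluenceDraw",
    "agent_estimate",
    "sample_influence",
    "transition_schedule",
    "agent_final_decision",
    "SUSCEPTIBLE_MIXTURE",
    "UNSUSCEPTIBLE_MIXTURE",
]

logger = logging.getLogger(__name__)

# (probability, (low, high)) pairs; probabilities sum to 1, intervals
# tile [0, 1] without overlap.
SUSCEPTIBLE_MIXTURE: tuple[tuple[float, tuple[float, float]], ...] = (
    (0.45, (0.75, 1.0)),
    (0.35, (0.5, 0.75)),
    (0.15, (0.25, 0.5)),
    (0.05, (0.0, 0.25)),
)
UNSUSCEPTIBLE_MIXTURE: tuple[tuple[float, tuple[float, float]], ...] = (
    (0.80, (0.0, 0.25)),
    (0.15, (0.25, 0.5)),
    (0.05, (0.5, 0.75)),
)

_MAX_RESAMPLE_ITER = 1000


@dataclass
class AgentParams:
    estimate_sd: float = 1.52
    resample_threshold: float = 0.5
    resample_prob: float = 0.5
    mixtures: dict[Condition, tuple[tuple[float, tuple[float, float]], ...]] = field(
        default_factory=lambda: {
            Condition.SUSCEPTIBLE: SUSCEPTIBLE_MIXTURE,
            Condition.UNSUSCEPTIBLE: UNSUSCEPTIBLE_MIXTURE,
        }
    )

    def __post_init__(self) -> None:
        if self.estimate_sd <= 0:
            raise ValueError("estimate_sd must be positive")
        if not 0 <= self.resample_prob <= 1:
            raise ValueError("resample_prob must be a probability")
        for cond, mixture in self.mixtures.items():
            probs = [p for p, _ in mixture]
            if not np.isclose(sum(probs), 1.0):
                raise ValueError(f"mixture probabilities for {cond} sum to {sum(probs)}")
            intervals = sorted(iv for _, iv in mixture)
            for (lo, hi) in intervals:
                if not (0 <= lo < hi <= 1):
                    raise ValueError(f"interval ({lo}, {hi}) not within [0, 1]")
            for (_, hi1), (lo2, _) in zip(intervals, intervals[1:]):
                if lo2 < hi1:
                    raise ValueError("mixture intervals overlap")


@dataclass(frozen=True)
class AgentEstimate:
    value: float
    resampled: bool


@dataclass(frozen=True)
class InfluenceDraw:
    i: float
    condition: Condition
    interval_index: int


def agent_estimate(
    s: float,
    participant_estimate: float,
    params: AgentParams,
    rng: np.random.Generator,
) -> AgentEstimate:
    """Draw the agent's perceptual estimate for a stimulus of length ``s``.

    The draw is Normal(s, estimate_sd).  If it lands within
    ``resample_threshold`` of the participant's estimate, then with
    probability ``resample_prob`` it is redrawn until it lands outside
    that band (loop bounded to keep degenerate inputs safe).
    """
    if s <= 0:
        raise ValueError("stimulus length must be positive")
    draw = rng.normal(s, params.estimate_sd)
    resampled = False
    if abs(draw - participant_estimate) < params.resample_threshold:
        if rng.random() < params.resample_prob:
            for _ in range(_MAX_RESAMPLE_ITER):
                draw = rng.normal(s, params.estimate_sd)
                resampled = True
                if abs(draw - participant_estimate) >= params.resample_threshold:
                    break
            else:
                warnings.warn(
                    "agent estimate resampling hit the iteration bound; "
                    "returning the last draw",
                    RuntimeWarning,
                    stacklevel=2,
                )
    if not 0.0 <= draw <= SCREEN_WIDTH_CM:
        logger.warning("agent estimate %.3f clipped to screen bounds", draw)
        draw = float(np.clip(draw, 0.0, SCREEN_WIDTH_CM))
    return AgentEstimate(value=float(draw), resampled=resampled)


def sample_influence(
    condition: Condition,
    params: AgentParams,
    rng: np.random.Generator,
    last_condition: Condition | None = None,
) -> InfluenceDraw:
    """Two-stage draw of the agent's influence for one observation turn.

    An interval is picked by its mixture probability, then the value is
    uniform within the interval.  The FINAL condition reuses the mixture
    of the last main condition faced, which must be supplied.
    """
    effective = condition
    if condition is Condition.FINAL:
        if last_condition not in (Condition.SUSCEPTIBLE, Condition.UNSUSCEPTIBLE):
            raise ValueError(
                "FINAL condition requires last_condition of SUSCEPTIBLE or UNSUSCEPTIBLE"
            )
        effective = last_condition
    if effective not in params.mixtures:
        raise ValueError(
            f"no influence mixture for condition {condition}; the transition "
            "block uses its own fixed schedule"
        )
    mixture = params.mixtures[effective]
    probs = np.array([p for p, _ in mixture])
    idx = int(rng.choice(len(mixture), p=probs))
    lo, hi = mixture[idx][1]
    return InfluenceDraw(i=float(rng.uniform(lo, hi)), condition=condition, interval_index=idx)


def transition_schedule(direction: str) -> list[tuple[float, float]]:
    """The fixed 11-interval influence schedule of the transition block.

    ``"S_TO_U"``: 2 draws from [0.75, 1], 2 from [0.5, 0.75], 3 from
    [0.25, 0.5], 4 from [0, 0.25], in this exact order.  ``"U_TO_S"``
    presents the same intervals in the opposite order.
    """
    descending = (
        [(0.75, 1.0)] * 2 + [(0.5, 0.75)] * 2 + [(0.25, 0.5)] * 3 + [(0.0, 0.25)] * 4
    )
    if direction == "S_TO_U":
        return descending
    if direction == "U_TO_S":
        return descending[::-1]
    raise ValueError(f"direction must be 'S_TO_U' or 'U_TO_S', got {direction!r}")


def agent_final_decision(
    agent_estimate: float, participant_estimate: float, i: float
) -> float:
    """Shift the agent's estimate toward the participant's by fraction ``i``.

    i = 0 keeps the agent's own estimate; i = 1 adopts the participant's.
    """
    if not 0.0 <= i <= 1.0:
        raise ValueError(f"influence must be in [0, 1], got {i}")
    return agent_estimate + i * (participant_estimate - agent_estimate)
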