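"""Trial/block/turn schedules for the three tasks of one session.

A session always runs the solo estimation task, then the joint task in
which the participant makes every final decision, then the reciprocal
task in which final decisions alternate between participant and agent.
Schedule construction is fully deterministic; only cohort-level
participant ordering consumes randomness.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "TaskKind",
    "Condition",
    "TurnKind",
    "Group",
    "ConditionOrder",
    "ScheduleSlot",
    "SessionSchedule",
    "build_session",
    "build_cohort",
    "schedule_to_frame",
    "N_PERCEPTUAL_TRIALS",
    "N_SOCIAL_TRIALS",
    "N_RECIPROCAL_TRIALS",
    "MAIN_BLOCK_TRIALS",
    "TRANSITION_TRIALS",
    "FINAL_BLOCK_TRIALS",
    "PAUSE_EVERY",
]

N_PERCEPTUAL_TRIALS = 66
N_SOCIAL_TRIALS = 66
MAIN_BLOCK_TRIALS = 66
TRANSITION_TRIALS = 22
FINAL_BLOCK_TRIALS = 22
N_RECIPROCAL_TRIALS = 2 * MAIN_BLOCK_TRIALS + TRANSITION_TRIALS + FINAL_BLOCK_TRIALS

#: Trials between rest pauses in the reciprocal task (annotation only).
PAUSE_EVERY = 22

# Display timing constants, recorded as metadata only (seconds unless noted).
TIMING_METADATA = {
    "disk_flash_ms": 200,
    "inter_stimulus_interval_ms": 200,
    "partner_estimate_delay_s": (2.50, 2.75),
    "partner_final_decision_delay_s": (3.75, 4.50),
    "response_visibility_s": 1.0,
}


class TaskKind(enum.Enum):
    PERCEPTUAL_INFERENCE = "perceptual_inference"
    SOCIAL_INFLUENCE = "social_influence"
    RECIPROCAL = "reciprocal"


class Condition(enum.Enum):
    BASELINE = "baseline"
    SUSCEPTIBLE = "susceptible"
    TRANSITION = "transition"
    UNSUSCEPTIBLE = "unsusceptible"
    FINAL = "final"


class TurnKind(enum.Enum):
    SOLO = "solo"
    DECISION = "decision"
    OBSERVATION = "observation"


class Group(enum.Enum):
    COMPUTER = "computer"
    ROBOT = "robot"


class ConditionOrder(enum.Enum):
    SUSCEPTIBLE_FIRST = "susceptible_first"
    UNSUSCEPTIBLE_FIRST = "unsusceptible_first"


@dataclass(frozen=True)
class ScheduleSlot:
    task: TaskKind
    block_index: int
    condition: Condition | None
    turn_kind: TurnKind
    trial_index: int  # 0-based within task
    pause_after: bool = False
    rating_prompt: bool = False


@dataclass
class SessionSchedule:
    participant_id: str
    group: Group
    condition_order: ConditionOrder
    slots: list[ScheduleSlot] = field(default_factory=list)

    def task_slots(self, task: TaskKind) -> list[ScheduleSlot]:
        return [s for s in self.slots if s.task is task]

    def __len__(self) -> int:
        return len(self.slots)

    def __iter__(self) -> Iterator[ScheduleSlot]:
        return iter(self.slots)

    @property
    def last_main_condition(self) -> Condition:
        """Condition of the main block immediately preceding the Final block."""
        if self.condition_order is ConditionOrder.SUSCEPTIBLE_FIRST:
            return Condition.UNSUSCEPTIBLE
        return Condition.SUSCEPTIBLE


def _coerce(value, enum_cls):
    if isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(value) if not isinstance(value, str) else enum_cls[value.upper()] \
            if value.upper() in enum_cls.__members__ else enum_cls(value.lower())
    except (KeyError, ValueError) as exc:
        valid = sorted(m.name for m in enum_cls)
        raise ValueError(
            f"invalid {enum_cls.__name__} label {value!r}; expected one of {valid}"
        ) from exc


def build_session(
    group: Group | str,
    condition_order: ConditionOrder | str,
    participant_id: str,
) -> SessionSchedule:
    """Build the deterministic slot structure for one participant.

    Solo task: 66 SOLO trials in three sub-blocks of 22.  Joint task: 66
    DECISION trials (baseline condition), same sub-block structure.
    Reciprocal task: two 66-trial main blocks (strict decision/observation
    alternation, decision first) separated by a 22-trial transition block,
    then a 22-trial final block of 11 observations followed by 11
    decisions.
    """
    group = _coerce(group, Group)
    condition_order = _coerce(condition_order, ConditionOrder)

    slots: list[ScheduleSlot] = []

    # Solo estimation task: three sub-blocks of 22 separated by pauses.
    for i in range(N_PERCEPTUAL_TRIALS):
        slots.append(
            ScheduleSlot(
                task=TaskKind.PERCEPTUAL_INFERENCE,
                block_index=i // PAUSE_EVERY,
                condition=None,
                turn_kind=TurnKind.SOLO,
                trial_index=i,
                pause_after=(i + 1) % PAUSE_EVERY == 0 and i + 1 < N_PERCEPTUAL_TRIALS,
                rating_prompt=i + 1 == N_PERCEPTUAL_TRIALS,
            )
        )

    # Joint task: every trial is a participant decision.
    for i in range(N_SOCIAL_TRIALS):
        slots.append(
            ScheduleSlot(
                task=TaskKind.SOCIAL_INFLUENCE,
                block_index=i // PAUSE_EVERY,
                condition=Condition.BASELINE,
                turn_kind=TurnKind.DECISION,
                trial_index=i,
                pause_after=(i + 1) % PAUSE_EVERY == 0 and i + 1 < N_SOCIAL_TRIALS,
                rating_prompt=i + 1 == N_SOCIAL_TRIALS,
            )
        )

    if condition_order is ConditionOrder.SUSCEPTIBLE_FIRST:
        first, second = Condition.SUSCEPTIBLE, Condition.UNSUSCEPTIBLE
    else:
        first, second = Condition.UNSUSCEPTIBLE, Condition.SUSCEPTIBLE

    reciprocal_plan: list[tuple[int, Condition, TurnKind]] = []
    # Main block 1 and 2 plus the transition: decision/observation strictly
    # alternating, decision first.
    for block, condition, n in (
        (0, first, MAIN_BLOCK_TRIALS),
        (1, Condition.TRANSITION, TRANSITION_TRIALS),
        (2, second, MAIN_BLOCK_TRIALS),
    ):
        for j in range(n):
            kind = TurnKind.DECISION if j % 2 == 0 else TurnKind.OBSERVATION
            reciprocal_plan.append((block, condition, kind))
    # Final block: 11 observation turns in a row, then 11 decision turns.
    for j in range(FINAL_BLOCK_TRIALS):
        kind = TurnKind.OBSERVATION if j < FINAL_BLOCK_TRIALS // 2 else TurnKind.DECISION
        reciprocal_plan.append((3, Condition.FINAL, kind))

    # Rating prompts: after 44 trials of each main block (last pause of the
    # block) and right after the transition block.
    rating_trials = {43, MAIN_BLOCK_TRIALS + TRANSITION_TRIALS - 1, MAIN_BLOCK_TRIALS + TRANSITION_TRIALS + 43}
    for i, (block, condition, kind) in enumerate(reciprocal_plan):
        slots.append(
            ScheduleSlot(
                task=TaskKind.RECIPROCAL,
                block_index=block,
                condition=condition,
                turn_kind=kind,
                trial_index=i,
                pause_after=(i + 1) % PAUSE_EVERY == 0 and i + 1 < N_RECIPROCAL_TRIALS,
                rating_prompt=i in rating_trials,
            )
        )

    return SessionSchedule(
        participant_id=participant_id,
        group=group,
        condition_order=condition_order,
        slots=slots,
    )


def build_cohort(n_per_group: int, seed: int) -> list[SessionSchedule]:
    """Build a counterbalanced cohort: both groups, half of each group
    gets the susceptible block first.

    ``seed`` only shuffles which participant slot receives which order;
    block composition is identical for every seed.
    """
    if n_per_group < 2 or n_per_group % 2 != 0:
        raise ValueError(
            f"n_per_group must be an even integer >= 2 for exact "
            f"counterbalancing, got {n_per_group}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    schedules: list[SessionSchedule] = []
    for group in (Group.COMPUTER, Group.ROBOT):
        orders = [ConditionOrder.SUSCEPTIBLE_FIRST, ConditionOrder.UNSUSCEPTIBLE_FIRST] * (
            n_per_group // 2
        )
        orders = [orders[i] for i in rng.permutation(n_per_group)]
        for i, order in enumerate(orders):
            pid = f"{group.value}_{i:03d}"
            schedules.append(build_session(group, order, pid))
    return schedules


def schedule_to_frame(schedules: SessionSchedule | list[SessionSchedule]) -> pd.DataFrame:
    """Export schedules as a tidy table (trial_index is 0-based within task)."""
    if isinstance(schedules, SessionSchedule):
        schedules = [schedules]
    rows = []
    for sched in schedules:
        for slot in sched.slots:
            rows.append(
                {
                    "participant_id": sched.participant_id,
                    "group": sched.group.value,
                    "condition_order": sched.condition_order.value,
                    "task": slot.task.value,
                    "block": slot.block_index,
                    "condition": slot.condition.value if slot.condition else "",
                    "turn_kind": slot.turn_kind.value,
                    "trial_index": slot.trial_index,
                    "pause_after": slot.pause_after,
                    "rating_prompt": slot.rating_prompt,
                }
            )
    return pd.DataFrame(rows)
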