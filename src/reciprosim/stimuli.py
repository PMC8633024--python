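"""Visual stimulus lengths and screen geometry.

Target lengths come from an 11-value grid (8 to 16 cm, step 0.8 cm,
design mean exactly 12 cm).  A session presents each length equally
often in a seeded shuffled order, so per-length statistics are always
computable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Stimulus",
    "stimulus_grid",
    "generate_stimuli",
    "SCREEN_WIDTH_CM",
    "SCREEN_HEIGHT_CM",
    "OFFSET_RANGE_CM",
    "DESIGN_MEAN_CM",
]

SCREEN_WIDTH_CM = 43.69
SCREEN_HEIGHT_CM = 24.07
DISK_DIAMETER_CM = 0.57
OFFSET_RANGE_CM = (0.6, 6.6)
GRID_MIN_CM = 8.0
GRID_MAX_CM = 16.0
GRID_STEP_CM = 0.8
N_LENGTHS = 11
DESIGN_MEAN_CM = 12.0


@dataclass(frozen=True)
class Stimulus:
    """One trial's target segment: length ``s`` and horizontal placement."""

    s: float
    first_disk_offset: float
    trial_index: int

    def __post_init__(self) -> None:
        lo, hi = OFFSET_RANGE_CM
        if not lo <= self.first_disk_offset <= hi:
            raise ValueError(
                f"first_disk_offset {self.first_disk_offset} outside [{lo}, {hi}]"
            )


def stimulus_grid() -> np.ndarray:
    """The 11 target lengths in cm, ascending."""
    grid = GRID_MIN_CM + GRID_STEP_CM * np.arange(N_LENGTHS)
    return np.round(grid, 10)


def generate_stimuli(n_trials: int, seed: int | np.random.Generator) -> list[Stimulus]:
    """Balanced shuffled stimulus sequence for one task.

    Each grid length appears exactly ``n_trials / 11`` times; the order
    and the first-disk offsets are drawn from ``seed``.
    """
    if n_trials % N_LENGTHS != 0:
        raise ValueError(
            f"n_trials must be a multiple of {N_LENGTHS} so every length "
            f"appears equally often, got {n_trials}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = np.tile(stimulus_grid(), n_trials // N_LENGTHS)
    rng.shuffle(lengths)
    offsets = rng.uniform(*OFFSET_RANGE_CM, size=n_trials)
    return [
        Stimulus(s=float(s), first_disk_offset=float(off), trial_index=i)
        for i, (s, off) in enumerate(zip(lengths, offsets))
    ]
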