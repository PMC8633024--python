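"""Behavioral indices computed from trial logs.

All lengths are in cm.  The influence index is the signed adjustment of
a final decision toward the partner divided by the distance between the
two estimates; trials with coincident estimates are flagged invalid and
excluded from influence analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimuli import DESIGN_MEAN_CM

__all__ = [
    "InfluenceRecord",
    "influence_index",
    "estimation_error",
    "regression_index",
    "underestimation",
    "normalized_response_distance",
    "binned_standardized_influence",
    "DISTANCE_BIN_EDGES",
]

#: Degenerate-distance threshold below which influence is undefined (cm).
DEGENERATE_DISTANCE_CM = 1e-6

#: Half-open standardized-distance bins, step 0.05 SDs; the ninth bin is
#: open-ended above 0.40 SDs.
DISTANCE_BIN_EDGES = np.arange(0.0, 0.45 + 1e-12, 0.05)
N_DISTANCE_BINS = 9


@dataclass(frozen=True)
class InfluenceRecord:
    a: float
    d: float
    i: float
    valid: bool


def influence_index(own: float, other: float, final: float) -> InfluenceRecord:
    """Adjustment toward the partner divided by the distance between estimates.

    ``final`` must lie on the closed segment between ``own`` and
    ``other`` (tolerance 1e-9); anything else is a data-integrity error.
    """
    d = abs(other - own)
    if d < DEGENERATE_DISTANCE_CM:
        return InfluenceRecord(a=0.0, d=d, i=np.nan, valid=False)
    lo, hi = min(own, other), max(own, other)
    if not (lo - 1e-9 <= final <= hi + 1e-9):
        raise ValueError(
            f"final decision {final} outside the segment [{lo}, {hi}]"
        )
    a = (final - own) * np.sign(other - own)
    i = float(np.clip(a / d, 0.0, 1.0))
    return InfluenceRecord(a=float(a), d=float(d), i=i, valid=True)


def estimation_error(estimate: float, s: float) -> float:
    """Absolute error relative to the true length: |estimate - s| / s."""
    if np.any(np.asarray(s) <= 0):
        raise ValueError("stimulus length must be positive")
    return abs(estimate - s) / s


def regression_index(stimuli, responses) -> float:
    """Central-tendency strength: 1 minus the OLS slope of responses on stimuli.

    0 means veridical reproduction; 1 means complete regression to the
    mean (flat responses).
    """
    stimuli = np.asarray(stimuli, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if len(np.unique(stimuli)) < 3:
        raise ValueError("regression index needs >= 3 distinct stimulus values")
    slope = np.polyfit(stimuli, responses, 1)[0]
    return float(1.0 - slope)


def underestimation(responses) -> float:
    """Mean reproduced length minus the 12 cm design mean."""
    responses = np.asarray(responses, dtype=float)
    if responses.size == 0:
        raise ValueError("responses must be non-empty")
    return float(responses.mean() - DESIGN_MEAN_CM)


def normalized_response_distance(own: float, other: float, s: float) -> float:
    """Distance between the two estimates in units of the true length."""
    if np.any(np.asarray(s) <= 0):
        raise ValueError("stimulus length must be positive")
    return abs(own - other) / s


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=0)
    if sd == 0:
        warnings.warn(
            "z-score of a constant series defined as 0", RuntimeWarning, stacklevel=3
        )
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def binned_standardized_influence(records: pd.DataFrame) -> pd.DataFrame:
    """Within-subject standardized influence per standardized-distance bin.

    ``records`` needs columns participant_id, s, participant_estimate,
    agent_estimate, influence.  Per participant: the SD of the
    participant's estimates is computed for each stimulus length, each
    trial's |own - other| distance is expressed in units of that SD and
    assigned to one of nine half-open 0.05-SD bins (the last bin absorbs
    everything >= 0.40); influence is z-scored within participant and
    averaged per bin, then bin means are averaged across participants.
    Empty bins are reported as NaN.
    """
    required = {"participant_id", "s", "participant_estimate", "agent_estimate", "influence"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    per_participant = []
    for pid, grp in records.groupby("participant_id"):
        grp = grp.dropna(subset=["influence"]).copy()
        if grp.empty:
            continue
        sd_per_s = grp.groupby("s")["participant_estimate"].transform(lambda v: v.std(ddof=1))
        if (grp.groupby("s")["participant_estimate"].count() < 2).any():
            raise ValueError(
                f"participant {pid}: need >= 2 trials per stimulus length for SDs"
            )
        std_dist = (grp["participant_estimate"] - grp["agent_estimate"]).abs() / sd_per_s
        bins = np.minimum(
            np.floor(std_dist.to_numpy() / 0.05).astype(int), N_DISTANCE_BINS - 1
        )
        z_inf = _zscore(grp["influence"].to_numpy())
        frame = pd.DataFrame({"bin": bins, "z_influence": z_inf})
        means = frame.groupby("bin")["z_influence"].mean()
        means = means.reindex(range(N_DISTANCE_BINS))
        means.name = pid
        per_participant.append(means)
    if not per_participant:
        raise ValueError("no valid influence trials")
    table = pd.concat(per_participant, axis=1)
    out = pd.DataFrame(
        {
            "bin": range(N_DISTANCE_BINS),
            "bin_low_sd": DISTANCE_BIN_EDGES[:-1][: N_DISTANCE_BINS],
            "mean_z_influence": table.mean(axis=1, skipna=True).to_numpy(),
            "n_participants": table.notna().sum(axis=1).to_numpy(),
        }
    )
    return out
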