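"""Trial validity, response classification and response-rate statistics.

A trial is one 10 s stripe-motion phase.  Both classification rules share a
single distance threshold: 20% of the lane length, i.e. 27 mm for the
standard 135 mm lane.

Validity
    A larva is valid for a trial when its position at motion onset leaves at
    least the threshold distance of lane ahead in the direction of stripe
    motion — it must have room to respond.
Response
    A valid larva is responsive when it swims at least the threshold
    distance in the stripe direction during the trial window.  The default
    displacement metric is the maximal signed excursion from the onset
    position (a larva that swims out and returns still responded); net
    displacement (final minus onset) is available as an alternative.
Response rate
    Each larva sees four trials (two rounds, one rightward and one leftward
    motion each).  Larvae valid in at least three of the four trials are
    included, and their rate is 100 x responses / valid trials.

Both rule boundaries are inclusive ("at least" the threshold), applied with
a small numeric tolerance so that a displacement of exactly 27 mm counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .arena import ArenaGeometry
from .tracking import Trajectory

__all__ = [
    "TrialRecord",
    "LarvaResult",
    "classify_valid",
    "classify_response",
    "make_trial_record",
    "response_rate",
    "group_summary",
    "trials_to_dataframe",
    "results_to_dataframe",
]

#: Absolute tolerance on the two inclusive 27 mm boundaries.
BOUNDARY_TOL_MM = 1e-9

#: Trials whose analysis window has more than this fraction of detection gaps
#: are unscorable and treated as non-valid.
MAX_GAP_FRACTION = 0.5

TRIALS_PER_LARVA = 4

DisplacementMetric = Literal["max_excursion", "net"]
InclusionMode = Literal["at_least_3", "all_4"]


@dataclass(frozen=True)
class TrialRecord:
    """Outcome of one larva x one stripe-motion phase."""

    larva_id: int
    trial_id: int
    direction: int  # +1 right, -1 left
    onset_pos_mm: float
    max_signed_displacement_mm: float
    valid: bool
    responsive: bool
    scorable: bool = True

    def __post_init__(self) -> None:
        if self.responsive and not (self.valid and self.scorable):
            raise ValueError("a responsive trial must be valid and scorable")


@dataclass(frozen=True)
class LarvaResult:
    """Per-larva aggregate over its four trials."""

    larva_id: int
    n_valid: int
    n_responses: int
    response_rate_pct: float  # NaN when not included
    included: bool


def classify_valid(
    onset_pos_mm: float, direction: int, geometry: ArenaGeometry
) -> bool:
    """Does the onset position leave >= 27 mm of lane in the motion direction?"""
    if direction not in (+1, -1):
        raise ValueError(f"direction must be +1 or -1, got {direction}")
    if not 0.0 <= onset_pos_mm <= geometry.lane_length_mm:
        raise ValueError(
            f"onset position {onset_pos_mm} mm outside lane "
            f"[0, {geometry.lane_length_mm}]"
        )
    if direction == +1:
        distance_to_end = geometry.lane_length_mm - onset_pos_mm
    else:
        distance_to_end = onset_pos_mm
    return distance_to_end >= geometry.validity_threshold_mm - BOUNDARY_TOL_MM


def classify_response(
    traj: Trajectory,
    window_s: tuple[float, float],
    direction: int,
    geometry: ArenaGeometry,
    camera_fps: float,
    onset_pos_mm: float | None = None,
    metric: DisplacementMetric = "max_excursion",
) -> tuple[bool, float]:
    """Classify one valid trial; returns (responsive, displacement_mm).

    The trajectory is trial-aligned (sample 0 at motion onset); ``window_s``
    selects the scored time interval in seconds.  The onset position
    defaults to the trajectory value at the window's first frame (falling
    back to the first finite sample when the tracker has a leading gap).
    """
    if direction not in (+1, -1):
        raise ValueError(f"direction must be +1 or -1, got {direction}")
    i0 = int(round(window_s[0] * camera_fps))
    i1 = int(round(window_s[1] * camera_fps))
    samples = traj.pos_mm[i0:i1]
    if samples.size == 0:
        raise ValueError(f"empty analysis window {window_s}")
    finite = np.isfinite(samples)
    if not finite.any():
        raise ValueError("no tracked samples in the analysis window")
    if onset_pos_mm is None:
        onset_pos_mm = (
            samples[0] if np.isfinite(samples[0]) else samples[finite][0]
        )
    if metric == "max_excursion":
        displacement = float(np.max(direction * (samples[finite] - onset_pos_mm)))
    elif metric == "net":
        displacement = float(direction * (samples[finite][-1] - onset_pos_mm))
    else:
        raise ValueError(f"unknown displacement metric {metric!r}")
    responsive = displacement >= geometry.validity_threshold_mm - BOUNDARY_TOL_MM
    return responsive, displacement


def make_trial_record(
    traj: Trajectory,
    trial_id: int,
    direction: int,
    geometry: ArenaGeometry,
    camera_fps: float,
    window_s: tuple[float, float] | None = None,
    onset_pos_mm: float | None = None,
    metric: DisplacementMetric = "max_excursion",
    max_gap_fraction: float = MAX_GAP_FRACTION,
) -> TrialRecord:
    """Apply the full trial ruleset to one trial-aligned trajectory.

    A trial is scorable when an onset position is known and at most
    ``max_gap_fraction`` of the window frames are detection gaps; an
    unscorable trial counts as non-valid.
    """
    if window_s is None:
        window_s = (0.0, len(traj.pos_mm) / camera_fps)
    i0 = int(round(window_s[0] * camera_fps))
    i1 = int(round(window_s[1] * camera_fps))
    gap_fraction = 1.0 - float(np.mean(traj.detected[i0:i1]))
    if onset_pos_mm is None and np.isfinite(traj.pos_mm[i0]):
        onset_pos_mm = float(traj.pos_mm[i0])
    scorable = (
        onset_pos_mm is not None
        and np.isfinite(onset_pos_mm)
        and gap_fraction <= max_gap_fraction
    )
    if not scorable:
        return TrialRecord(
            larva_id=traj.larva_id,
            trial_id=trial_id,
            direction=direction,
            onset_pos_mm=float("nan") if onset_pos_mm is None else float(onset_pos_mm),
            max_signed_displacement_mm=float("nan"),
            valid=False,
            responsive=False,
            scorable=False,
        )
    onset_pos_mm = float(np.clip(onset_pos_mm, 0.0, geometry.lane_length_mm))
    valid = classify_valid(onset_pos_mm, direction, geometry)
    responsive, displacement = classify_response(
        traj, window_s, direction, geometry, camera_fps, onset_pos_mm, metric
    )
    return TrialRecord(
        larva_id=traj.larva_id,
        trial_id=trial_id,
        direction=direction,
        onset_pos_mm=onset_pos_mm,
        max_signed_displacement_mm=displacement,
        valid=valid,
        responsive=responsive and valid,
        scorable=True,
    )


def response_rate(
    trials: Sequence[TrialRecord],
    inclusion_mode: InclusionMode = "at_least_3",
    expected_trials: int = TRIALS_PER_LARVA,
) -> LarvaResult:
    """Aggregate one larva's four trials into its response rate.

    Only valid trials contribute to either count.  With the default
    inclusion mode a larva needs >= 3 valid trials out of 4 (generally: all
    but one); the stricter ``all_4`` mode requires every trial to be valid.
    """
    if len(trials) != expected_trials:
        raise ValueError(
            f"expected {expected_trials} trials per larva, got {len(trials)}"
        )
    larva_ids = {t.larva_id for t in trials}
    if len(larva_ids) != 1:
        raise ValueError(f"trials belong to multiple larvae: {sorted(larva_ids)}")
    n_valid = sum(t.valid for t in trials)
    n_responses = sum(t.responsive and t.valid for t in trials)
    min_valid = expected_trials - 1 if inclusion_mode == "at_least_3" else expected_trials
    included = n_valid >= min_valid
    rate = 100.0 * n_responses / n_valid if included else float("nan")
    return LarvaResult(
        larva_id=trials[0].larva_id,
        n_valid=n_valid,
        n_responses=n_responses,
        response_rate_pct=rate,
        included=included,
    )


def group_summary(results: Sequence[LarvaResult]) -> dict[str, float]:
    """Median and quartiles of response rates over included larvae."""
    rates = np.array([r.response_rate_pct for r in results if r.included])
    if rates.size == 0:
        return {
            "n_included": 0,
            "median_rate_pct": float("nan"),
            "q1_rate_pct": float("nan"),
            "q3_rate_pct": float("nan"),
        }
    return {
        "n_included": int(rates.size),
        "median_rate_pct": float(np.median(rates)),
        "q1_rate_pct": float(np.percentile(rates, 25)),
        "q3_rate_pct": float(np.percentile(rates, 75)),
    }


def trials_to_dataframe(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in trials])


def results_to_dataframe(results: Sequence[LarvaResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
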