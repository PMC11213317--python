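"""Ground-truthed synthetic arena recordings.

Emulates what the IR camera sees: a bright, uniform background (the lit
stripe display is invisible through the IR filter), faint horizontal lane
boundaries, and one dark larva blob per lane.  Larval behaviour is modelled
per trial: when a stripe-motion phase starts, each larva either responds —
swims at a constant speed in the stripe direction — or does not, in which
case it keeps up spontaneous exploratory swimming, modelled as a reflected
Gaussian random walk confined to a band around its position at phase onset.
The band keeps spontaneous excursions well below the response threshold while
keeping the larva moving, as real larvae do.

Every random draw derives from ``LarvaBehaviorParams.seed``; identical
parameters give bit-identical ground truth and rendered stacks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .arena import (
    DEFAULT_MARGIN_PX,
    ArenaGeometry,
    build_lane_map,
    frame_shape,
    lane_boundary_rows,
)
from .stimulus import PhaseSchedule, default_schedule

__all__ = [
    "LarvaBehaviorParams",
    "GroundTruth",
    "simulate_trajectories",
    "render_synthetic_stack",
    "write_simulation",
]

DEFAULT_CAMERA_FPS = 20.0

BACKGROUND_VALUE = 200
BLOB_VALUE = 50
BOUNDARY_VALUE = 170


@dataclass(frozen=True)
class LarvaBehaviorParams:
    """Behavioural parameters of simulated larvae.

    response_prob
        Probability that a larva follows the stripes in any one motion phase
        (drawn independently per larva and trial).
    swim_speed_mm_s
        Constant swim speed while responding.  Default 8 mm/s: a strong
        response that covers ~80 mm in a 10 s trial, far beyond the 27 mm
        response threshold.
    baseline_jitter_mm
        Per-frame step SD of the spontaneous random walk performed when not
        responding (and during stationary phases).  0 freezes the larva.
    response_jitter_mm
        Per-frame positional noise while responding.  Directed swimming is
        far steadier than free exploration, so the default (None) uses 20%
        of ``baseline_jitter_mm``; with zero baseline jitter responders move
        deterministically.
    wander_band_mm
        Half-width of the reflecting band confining spontaneous swimming
        around the phase-onset position.  Default 15 mm: ample spontaneous
        movement, but bounded safely below the 27 mm response threshold.
    blob_radius_px
        Radius of the rendered larva blob in camera pixels.  Default 5 px
        (2.5 mm at 2 px/mm), large enough to survive the radius-6 median
        denoising the tracker applies.
    start_position_mm
        Either a fixed position or "uniform": uniform over the central half
        of the lane, which leaves every larva valid in both directions.
    """

    response_prob: float = 0.5
    swim_speed_mm_s: float = 8.0
    baseline_jitter_mm: float = 1.5
    response_jitter_mm: float | None = None
    wander_band_mm: float = 15.0
    blob_radius_px: float = 5.0
    start_position_mm: float | str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.response_prob <= 1.0:
            raise ValueError("response_prob must be in [0, 1]")
        if self.swim_speed_mm_s < 0 or self.baseline_jitter_mm < 0:
            raise ValueError("speeds and jitter must be non-negative")
        if self.blob_radius_px <= 0:
            raise ValueError("blob_radius_px must be positive")
        if self.response_jitter_mm is not None and self.response_jitter_mm < 0:
            raise ValueError("response_jitter_mm must be non-negative")

    @property
    def effective_response_jitter_mm(self) -> float:
        if self.response_jitter_mm is None:
            return 0.2 * self.baseline_jitter_mm
        return self.response_jitter_mm


@dataclass
class GroundTruth:
    """True per-frame positions plus the per-trial intent table.

    positions_mm : (n_larvae, n_frames) array of positions along the lane.
    trials : one row per (larva, trial) with columns
        larva_id, trial_id, direction (+1 right / -1 left), onset_frame,
        window_frames, intended_response.
    """

    positions_mm: np.ndarray
    trials: pd.DataFrame
    camera_fps: float
    geometry: ArenaGeometry
    params: LarvaBehaviorParams

    @property
    def n_larvae(self) -> int:
        return self.positions_mm.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions_mm.shape[1]


def _reflect(d: np.ndarray | float, band: float) -> np.ndarray | float:
    """Fold displacements into [-band, band] by reflection."""
    if band <= 0:
        return np.clip(d, -band, band) if band == 0 else d
    period = 4.0 * band
    d = (np.asarray(d) + band) % period
    d = np.where(d > 2 * band, period - d, d) - band
    return d


def _phase_table(
    schedule: PhaseSchedule, camera_fps: float, rounds: int
) -> tuple[int, list[tuple[int, int, float]]]:
    """Total frames and (start_frame, n_frames, direction) per phase, over rounds."""
    per_round = schedule.n_frames(camera_fps)
    phases = []
    for r in range(rounds):
        f = r * per_round
        for kind, dur in schedule.phases:
            n = round(dur * camera_fps)
            direction = {"stationary": 0.0, "right": 1.0, "left": -1.0}[kind]
            phases.append((f, n, direction))
            f += n
    return rounds * per_round, phases


def simulate_trajectories(
    geometry: ArenaGeometry,
    params: LarvaBehaviorParams,
    schedule: PhaseSchedule | None = None,
    camera_fps: float = DEFAULT_CAMERA_FPS,
    rounds: int = 2,
) -> GroundTruth:
    """Simulate per-frame larva positions over ``rounds`` repeats of a schedule.

    Trials (= motion phases) are numbered 1..2*rounds in temporal order.
    A responding larva moves at ``direction * swim_speed_mm_s`` plus jitter;
    a non-responding larva (and every larva during stationary phases)
    performs the confined random walk described in the module docstring.
    Positions are clamped to [0, lane_length_mm].
    """
    if camera_fps <= 0:
        raise ValueError("camera_fps must be positive")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    schedule = schedule or default_schedule()
    rng = np.random.default_rng(params.seed)
    n = geometry.lane_count
    L = geometry.lane_length_mm
    n_frames, phases = _phase_table(schedule, camera_fps, rounds)
    n_trials = sum(1 for _, _, d in phases if d != 0.0)

    if params.start_position_mm == "uniform":
        start = rng.uniform(0.25 * L, 0.75 * L, size=n)
    else:
        start = np.full(n, float(params.start_position_mm))
    respond = rng.random(size=(n, n_trials)) < params.response_prob

    pos = np.empty((n, n_frames))
    x = start.copy()
    trial_rows = []
    trial_idx = 0
    drift_per_frame = params.swim_speed_mm_s / camera_fps
    for start_frame, n_ph, direction in phases:
        anchor = x.copy()
        if direction != 0.0:
            trial_id = trial_idx + 1
            responding = respond[:, trial_idx]
            for lid in range(n):
                trial_rows.append(
                    {
                        "larva_id": lid,
                        "trial_id": trial_id,
                        "direction": int(direction),
                        "onset_frame": start_frame,
                        "window_frames": n_ph,
                        "intended_response": bool(responding[lid]),
                    }
                )
            trial_idx += 1
        else:
            responding = np.zeros(n, dtype=bool)
        jitter_scale = np.where(
            responding, params.effective_response_jitter_mm, params.baseline_jitter_mm
        )
        for t in range(n_ph):
            steps = (
                rng.standard_normal(n) * jitter_scale
                if jitter_scale.any()
                else np.zeros(n)
            )
            # responders: steady drift + small noise; others: walk reflected in band
            drifted = x + direction * drift_per_frame + steps
            confined = anchor + _reflect(x - anchor + steps, params.wander_band_mm)
            x = np.where(responding, drifted, confined)
            x = np.clip(x, 0.0, L)
            pos[:, start_frame + t] = x
    trials = pd.DataFrame(trial_rows)
    return GroundTruth(
        positions_mm=pos,
        trials=trials,
        camera_fps=camera_fps,
        geometry=geometry,
        params=params,
    )


def render_synthetic_stack(
    truth: GroundTruth,
    geometry: ArenaGeometry | None = None,
    noise_sd: float = 0.0,
    margin_px: int = DEFAULT_MARGIN_PX,
    seed: int | None = None,
) -> np.ndarray:
    """Render ground truth as an 8-bit grayscale stack (T, H, W).

    Uniform bright background, faint lane-boundary rows, one dark disk per
    lane centred at the true position (edges anti-aliased by coverage), then
    Gaussian pixel noise of the given SD, clipped to [0, 255].
    """
    geometry = geometry or truth.geometry
    h, w = frame_shape(geometry, margin_px)
    lanes = build_lane_map(geometry, margin_px)
    r = truth.params.blob_radius_px
    rng = np.random.default_rng(truth.params.seed + 1 if seed is None else seed)

    base = np.full((h, w), float(BACKGROUND_VALUE))
    for row in lane_boundary_rows(geometry, margin_px):
        base[row, :] = BOUNDARY_VALUE

    n_larvae = truth.n_larvae
    if n_larvae > len(lanes):
        raise ValueError(f"{n_larvae} larvae but only {len(lanes)} lanes")

    pad = int(np.ceil(r)) + 1
    yy, xx = np.mgrid[-pad : pad + 1, -pad : pad + 1]
    stack = np.empty((truth.n_frames, h, w), dtype=np.uint8)
    centers_row = np.array([lanes[i].center_row for i in range(n_larvae)])
    for t in range(truth.n_frames):
        frame = base.copy()
        for i in range(n_larvae):
            cx = lanes[i].mm_to_px(truth.positions_mm[i, t])
            cy = centers_row[i]
            if not (0 <= cx < w and 0 <= cy < h):
                raise ValueError(
                    f"blob centre ({cx:.1f}, {cy:.1f}) outside raster "
                    f"{(h, w)}: geometry/calibration mismatch"
                )
            ix, iy = int(round(cx)), int(round(cy))
            dist = np.hypot(yy + iy - cy, xx + ix - cx)
            alpha = np.clip(r + 0.5 - dist, 0.0, 1.0)
            y0, y1 = iy - pad, iy + pad + 1
            x0, x1 = ix - pad, ix + pad + 1
            ay0, ax0 = max(0, -y0), max(0, -x0)
            y0, x0 = max(0, y0), max(0, x0)
            y1, x1 = min(h, y1), min(w, x1)
            sub = alpha[ay0 : ay0 + (y1 - y0), ax0 : ax0 + (x1 - x0)]
            region = frame[y0:y1, x0:x1]
            frame[y0:y1, x0:x1] = region + sub * (BLOB_VALUE - region)
        if noise_sd > 0:
            frame = frame + rng.standard_normal(frame.shape) * noise_sd
        stack[t] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
    return stack


def write_simulation(
    truth: GroundTruth,
    stack: np.ndarray,
    out_dir: str | Path,
    stem: str = "sim",
) -> dict[str, Path]:
    """Write the stack (multi-page TIFF), ground-truth CSVs and lane map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": out / f"{stem}_stack.tif",
        "truth": out / f"{stem}_truth.csv",
        "trials": out / f"{stem}_trials.csv",
        "lanes": out / f"{stem}_lanes.csv",
    }
    tifffile.imwrite(paths["stack"], stack, photometric="minisblack")
    frames = np.arange(truth.n_frames)
    records = pd.DataFrame(
        {
            "larva_id": np.repeat(np.arange(truth.n_larvae), truth.n_frames),
            "frame": np.tile(frames, truth.n_larvae),
            "true_pos_mm": truth.positions_mm.ravel(),
        }
    )
    records.to_csv(paths["truth"], index=False)
    truth.trials.to_csv(paths["trials"], index=False)
    build_lane_map(truth.geometry).to_csv(paths["lanes"])
    return paths
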