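"""End-to-end orchestration: track -> classify -> summarise.

A :class:`RunConfig` captures every parameter of a run and round-trips
through YAML, so a persisted config fully reproduces its outputs.  The
pipeline consumes a trial-aligned recording of the whole session (the camera
runs continuously over the schedule's rounds), cuts out each stripe-motion
window, tracks all lanes, applies the validity/response rules, and writes
per-trial, per-larva and summary tables plus a time-coloured projection per
trial for visual QC.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .arena import ArenaGeometry, LaneMap, build_lane_map
from .response import (
    DisplacementMetric,
    InclusionMode,
    LarvaResult,
    TrialRecord,
    group_summary,
    make_trial_record,
    response_rate,
    results_to_dataframe,
    trials_to_dataframe,
)
from .stimulus import PhaseSchedule, StimulusConfig, default_schedule
from .tracking import (
    DEFAULT_MIN_AMPLITUDE,
    DEFAULT_MIN_BLOB_AREA,
    DEFAULT_WINDOW_FRAMES,
    FrameStack,
    read_stack,
    track_window,
    trajectories_to_dataframe,
    trajectory_projection,
)

__all__ = ["RunConfig", "TrialWindow", "trial_windows", "run_pipeline", "PipelineResult"]

logger = logging.getLogger("omr_assay")


@dataclass(frozen=True)
class TrialWindow:
    trial_id: int
    direction: int
    onset_frame: int
    n_frames: int


@dataclass(frozen=True)
class RunConfig:
    """Complete, serialisable description of one analysis run."""

    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    geometry: ArenaGeometry = field(default_factory=ArenaGeometry)
    schedule: PhaseSchedule = field(default_factory=default_schedule)
    rounds: int = 2
    camera_fps: float = 20.0
    window_frames: int = DEFAULT_WINDOW_FRAMES
    min_blob_area_px: int = DEFAULT_MIN_BLOB_AREA
    min_amplitude: float = DEFAULT_MIN_AMPLITUDE
    metric: DisplacementMetric = "max_excursion"
    inclusion_mode: InclusionMode = "at_least_3"
    max_gap_fraction: float = 0.5
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schedule"] = [[kind, float(dur)] for kind, dur in self.schedule.phases]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "schedule" in d:
            d["schedule"] = PhaseSchedule(
                phases=tuple((kind, float(dur)) for kind, dur in d["schedule"])
            )
        if "stimulus" in d and isinstance(d["stimulus"], dict):
            d["stimulus"] = StimulusConfig(**d["stimulus"])
        if "geometry" in d and isinstance(d["geometry"], dict):
            d["geometry"] = ArenaGeometry(**d["geometry"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"run config not found: {path}")
        return cls.from_dict(yaml.safe_load(path.read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def trial_windows(
    schedule: PhaseSchedule, camera_fps: float, rounds: int = 2
) -> list[TrialWindow]:
    """Frame windows of every stripe-motion phase over repeated rounds."""
    per_round = schedule.n_frames(camera_fps)
    windows = []
    trial_id = 1
    for r in range(rounds):
        f = r * per_round
        for kind, dur in schedule.phases:
            n = round(dur * camera_fps)
            if kind != "stationary":
                windows.append(
                    TrialWindow(
                        trial_id=trial_id,
                        direction=+1 if kind == "right" else -1,
                        onset_frame=f,
                        n_frames=n,
                    )
                )
                trial_id += 1
            f += n
    return windows


@dataclass
class PipelineResult:
    trials: list[TrialRecord]
    larvae: list[LarvaResult]
    summary: dict[str, float]
    trajectories: pd.DataFrame
    out_dir: Path | None = None

    @property
    def trial_table(self) -> pd.DataFrame:
        return trials_to_dataframe(self.trials)

    @property
    def larva_table(self) -> pd.DataFrame:
        return results_to_dataframe(self.larvae)


def run_pipeline(
    config: RunConfig,
    stack: FrameStack | str | Path,
    lanes: LaneMap | str | Path | None = None,
    out_dir: str | Path | None = None,
    write_projections: bool = True,
) -> PipelineResult:
    """Track, classify and summarise one session recording.

    ``stack`` covers the full schedule (all rounds) and is trial-aligned:
    frame 0 is the start of the schedule.  ``lanes`` defaults to the lane
    map implied by the arena geometry (correct for simulator output); for
    real recordings pass a calibrated lane ROI CSV.
    """
    if isinstance(stack, (str, Path)):
        stack = read_stack(stack, camera_fps=config.camera_fps)
    if lanes is None:
        lanes = build_lane_map(config.geometry)
    elif isinstance(lanes, (str, Path)):
        lanes = LaneMap.from_csv(lanes)
    lanes.validate_against(stack.frame_shape)

    windows = trial_windows(config.schedule, config.camera_fps, config.rounds)
    needed = max(w.onset_frame + min(w.n_frames, config.window_frames) for w in windows)
    if len(stack) < needed:
        raise ValueError(
            f"stack has {len(stack)} frames but the schedule x {config.rounds} "
            f"rounds needs at least {needed}"
        )

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    all_trials: list[TrialRecord] = []
    traj_tables = []
    for w in windows:
        n = min(w.n_frames, config.window_frames)
        raw = FrameStack(
            frames=stack.frames[w.onset_frame : w.onset_frame + n],
            camera_fps=config.camera_fps,
        )
        onsets, trajectories, processed = track_window(
            raw, lanes, config.min_blob_area_px, config.min_amplitude
        )
        logger.info(
            "trial %d (dir %+d): %d/%d lanes with onset detection",
            w.trial_id,
            w.direction,
            int(np.isfinite(onsets).sum()),
            len(lanes),
        )
        for i, traj in enumerate(trajectories):
            onset = onsets[i] if np.isfinite(onsets[i]) else None
            all_trials.append(
                make_trial_record(
                    traj,
                    trial_id=w.trial_id,
                    direction=w.direction,
                    geometry=config.geometry,
                    camera_fps=config.camera_fps,
                    onset_pos_mm=onset,
                    metric=config.metric,
                    max_gap_fraction=config.max_gap_fraction,
                )
            )
        traj_tables.append(
            trajectories_to_dataframe(trajectories, config.camera_fps, w.trial_id)
        )
        if out is not None and write_projections:
            iio.imwrite(
                out / f"trial_{w.trial_id:02d}_projection.png",
                trajectory_projection(processed),
            )

    larvae = []
    by_larva: dict[int, list[TrialRecord]] = {}
    for t in all_trials:
        by_larva.setdefault(t.larva_id, []).append(t)
    for larva_id in sorted(by_larva):
        larvae.append(
            response_rate(
                by_larva[larva_id],
                config.inclusion_mode,
                expected_trials=2 * config.rounds,
            )
        )
    summary = group_summary(larvae)
    trajectories_df = pd.concat(traj_tables, ignore_index=True)

    result = PipelineResult(
        trials=all_trials,
        larvae=larvae,
        summary=summary,
        trajectories=trajectories_df,
        out_dir=out,
    )
    if out is not None:
        result.trial_table.to_csv(out / "trials.csv", index=False)
        result.larva_table.to_csv(out / "larvae.csv", index=False)
        pd.DataFrame([summary]).to_csv(out / "summary.csv", index=False)
        trajectories_df.to_csv(out / "trajectories.csv", index=False)
        config.to_yaml(out / "run_config.yaml")
        _write_run_log(out / "run_log.json", config)
    return result


def _write_run_log(path: Path, config: RunConfig) -> None:
    import numpy
    import pandas
    import scipy
    import skimage

    log = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "scikit-image": skimage.__version__,
        },
    }
    path.write_text(json.dumps(log, indent=2))
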