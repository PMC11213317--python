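"""Larval tracking on multi-page TIFF stacks.

The processing chain mirrors the original batch recipe for these recordings:
take the analysis window covering one 10 s stripe-motion phase, subtract the
window's first frame from every frame to remove the static background,
median-filter with a radius-6 circular kernel to suppress noise, and flip
polarity so the larva is the brightest object.  On top of that, an explicit
detection rule (per-lane Otsu threshold + largest connected component)
converts each frame into a position along the lane axis in mm.

Because the background reference is the first frame of the window, a larva
sitting exactly where it started leaves no difference signal; such frames are
recorded as gaps, interior gaps are linearly interpolated, and the larva's
position at motion onset is instead detected directly on the raw first frame
(dark blob on bright background), which is also how validity is judged on the
bench.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.filters import rank, threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk

from .arena import LaneMap, LaneROI

__all__ = [
    "FrameStack",
    "Trajectory",
    "read_stack",
    "extract_analysis_window",
    "subtract_background",
    "denoise_and_polarize",
    "detect_positions",
    "detect_onset_positions",
    "trajectory_projection",
    "track_window",
    "trajectories_to_dataframe",
]

DEFAULT_WINDOW_FRAMES = 200  # 10 s of motion at the 20 fps camera
DEFAULT_MEDIAN_RADIUS = 6
DEFAULT_MIN_BLOB_AREA = 9
#: Minimum lane max-minus-median intensity for a frame to count as a detection.
DEFAULT_MIN_AMPLITUDE = 30.0


@dataclass
class FrameStack:
    """Ordered grayscale frames plus acquisition metadata."""

    frames: np.ndarray  # (T, H, W)
    camera_fps: float = 20.0

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError(f"expected (T, H, W) stack, got shape {self.frames.shape}")
        if self.camera_fps <= 0:
            raise ValueError("camera_fps must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class Trajectory:
    """Per-frame position of one larva along its lane axis.

    ``pos_mm`` is NaN where no blob qualified and the gap could not be
    interpolated (leading/trailing gaps).  ``detected`` marks genuine
    detections; ``interpolated`` marks gap-filled samples.
    """

    larva_id: int
    pos_mm: np.ndarray
    blob_area_px: np.ndarray
    detected: np.ndarray
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.pos_mm), dtype=bool)

    @property
    def gap_fraction(self) -> float:
        return 1.0 - float(np.mean(self.detected))


def read_stack(path: str | Path, camera_fps: float = 20.0) -> FrameStack:
    """Read a multi-page grayscale TIFF into a FrameStack."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"video stack not found: {path}")
    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        frames = frames[None]
    return FrameStack(frames=frames, camera_fps=camera_fps)


def extract_analysis_window(stack: FrameStack, window_frames: int = DEFAULT_WINDOW_FRAMES) -> FrameStack:
    """First ``window_frames`` frames of a trial-aligned stack.

    The stack is expected to start at stripe-motion onset; the default window
    of 200 frames covers the full 10 s motion phase at 20 fps.
    """
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    if len(stack) < window_frames:
        raise ValueError(
            f"stack has {len(stack)} frames but the analysis window "
            f"requires {window_frames}"
        )
    return FrameStack(frames=stack.frames[:window_frames], camera_fps=stack.camera_fps)


def subtract_background(stack: FrameStack) -> FrameStack:
    """Signed difference of every frame against frame 0, in float32.

    Output frame 0 is identically zero; a dark larva appears as a negative
    imprint at its current position and a positive ghost at its frame-0
    position.
    """
    if len(stack) < 1:
        raise ValueError("empty stack")
    f = stack.frames.astype(np.float32)
    return FrameStack(frames=f - f[0], camera_fps=stack.camera_fps)


def denoise_and_polarize(
    stack: FrameStack, radius: int = DEFAULT_MEDIAN_RADIUS
) -> FrameStack:
    """Median-filter each frame (circular kernel) and flip polarity.

    After the flip the larva's current position is the maximal-intensity
    object and the frame-0 ghost is negative.  The median is computed on an
    8-bit quantisation of the signed difference (the median commutes with
    monotone maps, so this only coarsens intensities to 2 gray levels, which
    is far below the detection amplitude).
    """
    footprint = disk(radius)
    # signed range [-255, 255] -> [0, 255] with 0 difference at 128
    q = np.clip(np.rint(stack.frames / 2.0) + 128.0, 0, 255).astype(np.uint8)
    out = np.empty_like(stack.frames, dtype=np.float32)
    for t in range(len(stack)):
        med = rank.median(q[t], footprint=footprint).astype(np.float32)
        out[t] = -(med - 128.0) * 2.0
    return FrameStack(frames=out, camera_fps=stack.camera_fps)


def _detect_in_lane(
    image: np.ndarray,
    lane: LaneROI,
    min_blob_area_px: int,
    min_amplitude: float,
) -> tuple[float, float] | None:
    """Detect the larva in one lane of one frame.

    Returns (position_mm, blob_area_px) or None.  Pixels below zero are
    ignored (the background-subtraction ghost); the lane is thresholded with
    Otsu, the largest connected component of sufficient area is kept, and the
    position is its intensity-weighted centroid projected on the lane axis.
    """
    roi = np.clip(image[lane.row0 : lane.row1, lane.col0 : lane.col1], 0.0, None)
    if roi.size == 0:
        return None
    amplitude = float(roi.max() - np.median(roi))
    if amplitude < min_amplitude:
        return None
    thr = threshold_otsu(roi)
    mask = roi > thr
    labels = label(mask, connectivity=2)
    best = None
    for region in regionprops(labels):
        if region.area < min_blob_area_px:
            continue
        if best is None or region.area > best.area:
            best = region
    if best is None:
        return None
    component = labels == best.label
    weights = np.where(component, roi - thr, 0.0)
    total = weights.sum()
    if total <= 0:
        return None
    cols = np.arange(roi.shape[1])
    cx = float((weights.sum(axis=0) * cols).sum() / total)
    pos_mm = lane.px_to_mm(cx + lane.col0)
    return pos_mm, float(best.area)


def _interpolate_gaps(pos: np.ndarray, detected: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linearly fill interior gaps; leading/trailing gaps stay NaN."""
    out = pos.copy()
    interpolated = np.zeros(len(pos), dtype=bool)
    idx = np.flatnonzero(detected)
    if len(idx) >= 2:
        interior = np.zeros(len(pos), dtype=bool)
        interior[idx[0] : idx[-1] + 1] = True
        fill = interior & ~detected
        if fill.any():
            out[fill] = np.interp(np.flatnonzero(fill), idx, pos[idx])
            interpolated = fill
    return out, interpolated


def detect_positions(
    stack: FrameStack,
    lanes: LaneMap,
    min_blob_area_px: int = DEFAULT_MIN_BLOB_AREA,
    min_amplitude: float = DEFAULT_MIN_AMPLITUDE,
) -> list[Trajectory]:
    """Per-lane larva positions for every frame of a preprocessed stack."""
    lanes.validate_against(stack.frame_shape)
    n_frames = len(stack)
    trajectories = []
    for lane in lanes:
        pos = np.full(n_frames, np.nan)
        area = np.zeros(n_frames)
        detected = np.zeros(n_frames, dtype=bool)
        for t in range(n_frames):
            hit = _detect_in_lane(stack.frames[t], lane, min_blob_area_px, min_amplitude)
            if hit is not None:
                pos[t], area[t] = hit
                detected[t] = True
        filled, interpolated = _interpolate_gaps(pos, detected)
        trajectories.append(
            Trajectory(
                larva_id=lane.lane_id,
                pos_mm=filled,
                blob_area_px=area,
                detected=detected,
                interpolated=interpolated,
            )
        )
    return trajectories


def detect_onset_positions(
    raw_frame: np.ndarray,
    lanes: LaneMap,
    min_blob_area_px: int = DEFAULT_MIN_BLOB_AREA,
    min_amplitude: float = DEFAULT_MIN_AMPLITUDE,
) -> np.ndarray:
    """Larva position per lane from one raw frame (dark blob, bright field).

    Used on the first frame of the analysis window, where background
    subtraction is blind by construction.  Returns an array of positions in
    mm, NaN where no blob was found.
    """
    lanes.validate_against(raw_frame.shape)
    inverted = 255.0 - raw_frame.astype(np.float32)
    # re-zero on the background so the ghost-clipping in _detect_in_lane is a no-op
    inverted -= np.median(inverted)
    out = np.full(len(lanes), np.nan)
    for i, lane in enumerate(lanes):
        hit = _detect_in_lane(inverted, lane, min_blob_area_px, min_amplitude)
        if hit is not None:
            out[i] = hit[0]
    return out


def trajectory_projection(stack: FrameStack, colormap: str = "viridis") -> np.ndarray:
    """Time-coloured maximum-intensity projection of a preprocessed stack.

    Each pixel takes the colour of the frame where its (ghost-clipped)
    intensity peaks, scaled by that peak intensity — a quick visual QC of
    where each larva swam and when.  Returns an (H, W, 3) uint8 image.
    """
    from matplotlib import colormaps

    clipped = np.clip(stack.frames, 0.0, None)
    peak = clipped.max(axis=0)
    when = clipped.argmax(axis=0)
    n = max(len(stack) - 1, 1)
    cmap = colormaps[colormap]
    colors = cmap(when.astype(float) / n)[..., :3]
    scale = peak / peak.max() if peak.max() > 0 else peak
    return np.clip(np.rint(colors * scale[..., None] * 255.0), 0, 255).astype(np.uint8)


def track_window(
    raw_window: FrameStack,
    lanes: LaneMap,
    min_blob_area_px: int = DEFAULT_MIN_BLOB_AREA,
    min_amplitude: float = DEFAULT_MIN_AMPLITUDE,
) -> tuple[np.ndarray, list[Trajectory], FrameStack]:
    """Full tracking chain on one trial-aligned window.

    Returns (onset positions in mm, per-lane trajectories, preprocessed
    stack).  The preprocessed stack is returned so callers can render the
    projection without repeating the median filter.
    """
    onsets = detect_onset_positions(
        raw_window.frames[0], lanes, min_blob_area_px, min_amplitude
    )
    processed = denoise_and_polarize(subtract_background(raw_window))
    trajectories = detect_positions(processed, lanes, min_blob_area_px, min_amplitude)
    return onsets, trajectories, processed


def trajectories_to_dataframe(
    trajectories: list[Trajectory],
    camera_fps: float,
    trial_id: int | None = None,
) -> pd.DataFrame:
    """Long-format per-frame table (one row per larva and frame)."""
    rows = []
    for traj in trajectories:
        n = len(traj.pos_mm)
        df = pd.DataFrame(
            {
                "larva_id": traj.larva_id,
                "frame": np.arange(n),
                "time_s": np.arange(n) / camera_fps,
                "pos_mm": traj.pos_mm,
                "blob_area_px": traj.blob_area_px,
                "detected": traj.detected,
                "interpolated": traj.interpolated,
            }
        )
        if trial_id is not None:
            df.insert(1, "trial_id", trial_id)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)
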