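"""Moving-stripe stimulus generation.

Renders the alternating two-colour stripe pattern shown beneath the arena and
the standard motion protocol: 5 s stationary, 10 s drifting right, 5 s
stationary, 10 s drifting left.  Parameter semantics follow the display
convention of the stripe-pattern software the assay uses: widths and speeds
are specified in display pixels, one display pixel is 0.2 mm on the screen,
and 50 frames make one second, so a physical speed in mm/s converts to
``speed / (mm_per_display_px * display_fps)`` pixels per frame.

Stripes run perpendicular to the motion axis; "right" means the pattern
drifts toward increasing column index.  Contrast acts as the opacity of the
second colour composited over the first: at contrast 1 the two nominal
colours alternate, at contrast 0 the field is uniformly colour 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

import numpy as np
import tifffile

__all__ = [
    "StimulusConfig",
    "PhaseSchedule",
    "StimulusFrame",
    "default_schedule",
    "mm_per_s_to_px_per_frame",
    "stripe_width_mm_to_px",
    "render_frame",
    "render_sequence",
    "write_sequence_tiff",
]

PhaseKind = Literal["stationary", "right", "left"]

_DIRECTION = {"stationary": 0.0, "right": 1.0, "left": -1.0}


def parse_hex_color(s: str) -> np.ndarray:
    """'#RRGGBB' -> float array of 3 channels in [0, 255]."""
    t = s.lstrip("#")
    if len(t) != 6:
        raise ValueError(f"expected hex colour '#RRGGBB', got {s!r}")
    try:
        return np.array([int(t[i : i + 2], 16) for i in (0, 2, 4)], dtype=float)
    except ValueError as e:
        raise ValueError(f"invalid hex colour {s!r}") from e


@dataclass(frozen=True)
class StimulusConfig:
    """Stripe-pattern parameters.

    ``stripe_width_px`` is the width of one stripe, so the spatial period of
    the pattern along the motion axis is ``2 * stripe_width_px``.
    """

    stripe_width_px: int = 40
    color1: str = "#000000"
    color2: str = "#FFFFFF"
    contrast: float = 1.0
    speed_px_per_frame: float = 0.65
    display_fps: float = 50.0
    mm_per_display_px: float = 0.2
    canvas_width_px: int = 700
    canvas_height_px: int = 550

    def __post_init__(self) -> None:
        if self.stripe_width_px < 1:
            raise ValueError("stripe_width_px must be >= 1")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must be in [0, 1]")
        if self.speed_px_per_frame < 0:
            raise ValueError("speed_px_per_frame must be non-negative")
        if self.display_fps <= 0 or self.mm_per_display_px <= 0:
            raise ValueError("display_fps and mm_per_display_px must be positive")
        if self.canvas_width_px < 1 or self.canvas_height_px < 1:
            raise ValueError("canvas dimensions must be positive")
        parse_hex_color(self.color1)
        parse_hex_color(self.color2)

    @property
    def period_px(self) -> int:
        return 2 * self.stripe_width_px


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered (phase_kind, duration_s) protocol."""

    phases: tuple[tuple[PhaseKind, float], ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("schedule must contain at least one phase")
        for kind, dur in self.phases:
            if kind not in _DIRECTION:
                raise ValueError(f"unknown phase kind {kind!r}")
            if dur <= 0:
                raise ValueError(f"phase durations must be positive, got {dur}")

    @property
    def total_duration_s(self) -> float:
        return sum(d for _, d in self.phases)

    def n_frames(self, fps: float) -> int:
        return sum(round(d * fps) for _, d in self.phases)

    def motion_phases(self) -> list[tuple[int, PhaseKind, float]]:
        """(phase_index, kind, start_time_s) for every non-stationary phase."""
        out, t = [], 0.0
        for i, (kind, dur) in enumerate(self.phases):
            if kind != "stationary":
                out.append((i, kind, t))
            t += dur
        return out


@dataclass(frozen=True)
class StimulusFrame:
    raster: np.ndarray  # (H, W, 3) uint8
    frame_index: int
    phase_kind: PhaseKind
    accumulated_offset_px: float


def default_schedule() -> PhaseSchedule:
    """The standard protocol: 5 s still, 10 s right, 5 s still, 10 s left."""
    return PhaseSchedule(
        phases=(
            ("stationary", 5.0),
            ("right", 10.0),
            ("stationary", 5.0),
            ("left", 10.0),
        )
    )


def mm_per_s_to_px_per_frame(speed_mm_per_s: float, config: StimulusConfig) -> float:
    """Physical stripe speed (mm/s) -> display pixels per frame."""
    if speed_mm_per_s < 0:
        raise ValueError("speed must be non-negative")
    return speed_mm_per_s / (config.mm_per_display_px * config.display_fps)


def stripe_width_mm_to_px(width_mm: float, config: StimulusConfig) -> int:
    """Physical stripe width (mm) -> display pixels (nearest integer, >= 1)."""
    if width_mm <= 0:
        raise ValueError("width must be positive")
    px = round(width_mm / config.mm_per_display_px)
    if px < 1:
        raise ValueError(
            f"stripe width {width_mm} mm is below half a display pixel "
            f"({config.mm_per_display_px} mm/px) and cannot be rendered"
        )
    return px


def blended_color2(config: StimulusConfig) -> np.ndarray:
    """Colour 2 composited over colour 1 at opacity = contrast (float, 0-255)."""
    c1 = parse_hex_color(config.color1)
    c2 = parse_hex_color(config.color2)
    return config.contrast * c2 + (1.0 - config.contrast) * c1


def render_frame(
    config: StimulusConfig,
    offset_px: float,
    frame_index: int = 0,
    phase_kind: PhaseKind = "stationary",
) -> StimulusFrame:
    """Render one stripe frame at the given accumulated pattern offset.

    A column takes colour 1 when ``(col - round(offset)) mod 2w < w`` and
    the contrast-blended colour 2 otherwise.  The fractional offset is
    rounded at render time; no anti-aliasing.
    """
    w = config.stripe_width_px
    cols = np.arange(config.canvas_width_px)
    is_c1 = ((cols - round(offset_px)) % (2 * w)) < w
    c1 = np.rint(parse_hex_color(config.color1)).astype(np.uint8)
    c2 = np.rint(blended_color2(config)).astype(np.uint8)
    row = np.where(is_c1[:, None], c1[None, :], c2[None, :]).astype(np.uint8)
    raster = np.broadcast_to(
        row[None, :, :], (config.canvas_height_px, config.canvas_width_px, 3)
    ).copy()
    return StimulusFrame(
        raster=raster,
        frame_index=frame_index,
        phase_kind=phase_kind,
        accumulated_offset_px=float(offset_px),
    )


def iter_sequence(
    config: StimulusConfig, schedule: PhaseSchedule
) -> Iterator[StimulusFrame]:
    """Lazily render the frame sequence for a schedule.

    Each phase contributes ``round(duration * display_fps)`` frames.  The
    pattern offset advances by ``speed_px_per_frame`` after each frame of a
    motion phase (+ for right, - for left) and stays put in stationary
    phases, so the first frame of a motion phase still shows the offset the
    previous phase ended with.
    """
    offset = 0.0
    frame_index = 0
    for kind, dur in schedule.phases:
        n = round(dur * config.display_fps)
        step = _DIRECTION[kind] * config.speed_px_per_frame
        for _ in range(n):
            yield render_frame(config, offset, frame_index, kind)
            offset += step
            frame_index += 1


def render_sequence(
    config: StimulusConfig, schedule: PhaseSchedule
) -> list[StimulusFrame]:
    """Materialized :func:`iter_sequence` (use the iterator for long runs)."""
    return list(iter_sequence(config, schedule))


def write_sequence_tiff(
    frames: Iterable[StimulusFrame], path: str | Path
) -> int:
    """Write frames as a multi-page RGB TIFF; returns the frame count."""
    n = 0
    with tifffile.TiffWriter(str(path)) as tif:
        for f in frames:
            tif.write(f.raster, photometric="rgb", contiguous=True)
            n += 1
    return n
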