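"""Arena geometry and camera-frame lane layout.

The linear-pool arena holds one larva per lane.  Lanes are long, narrow
channels (defaults: 15 lanes, 135 mm x 5 mm) laid out side by side; in camera
frames the lane long axis runs horizontally (the stripe-motion axis) and
lanes are stacked vertically.  All positions along a lane are expressed in mm
from the left lane end; the mapping to camera pixels is an affine map per
lane carried by :class:`LaneMap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

__all__ = ["ArenaGeometry", "LaneROI", "LaneMap", "build_lane_map", "frame_shape"]

#: Blank border (px) around the lane block in simulator-rendered frames.
DEFAULT_MARGIN_PX = 16


@dataclass(frozen=True)
class ArenaGeometry:
    """Physical arena dimensions and the camera/validity calibration.

    The validity threshold used by both the trial-validity rule and the
    response rule is ``validity_fraction * lane_length_mm`` (27 mm at the
    defaults: 20% of a 135 mm lane).
    """

    lane_count: int = 15
    lane_length_mm: float = 135.0
    lane_width_mm: float = 5.0
    camera_px_per_mm: float = 2.0
    validity_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.lane_count < 1:
            raise ValueError(f"lane_count must be >= 1, got {self.lane_count}")
        if self.lane_length_mm <= 0 or self.lane_width_mm <= 0:
            raise ValueError("lane dimensions must be positive")
        if self.camera_px_per_mm <= 0:
            raise ValueError("camera_px_per_mm must be positive")
        if not 0.0 < self.validity_fraction <= 1.0:
            raise ValueError("validity_fraction must be in (0, 1]")

    @property
    def validity_threshold_mm(self) -> float:
        """Distance threshold shared by the validity and response rules."""
        return self.validity_fraction * self.lane_length_mm


@dataclass(frozen=True)
class LaneROI:
    """One lane's pixel rectangle plus its mm <-> px affine map.

    ``row0:row1`` / ``col0:col1`` is the half-open detection rectangle; a
    position ``pos_mm`` along the lane sits at column
    ``x_origin_px + pos_mm * px_per_mm``.
    """

    lane_id: int
    row0: int
    row1: int
    col0: int
    col1: int
    x_origin_px: float
    px_per_mm: float

    def px_to_mm(self, x_px: float) -> float:
        return (x_px - self.x_origin_px) / self.px_per_mm

    def mm_to_px(self, pos_mm: float) -> float:
        return self.x_origin_px + pos_mm * self.px_per_mm

    @property
    def center_row(self) -> float:
        return (self.row0 + self.row1 - 1) / 2.0


@dataclass
class LaneMap:
    """Ordered collection of lane ROIs covering one camera frame."""

    lanes: list[LaneROI] = field(default_factory=list)

    def __iter__(self) -> Iterator[LaneROI]:
        return iter(self.lanes)

    def __len__(self) -> int:
        return len(self.lanes)

    def __getitem__(self, i: int) -> LaneROI:
        return self.lanes[i]

    def validate_against(self, frame_hw: tuple[int, int]) -> None:
        """Raise if any lane rectangle falls outside a frame of shape (H, W)."""
        h, w = frame_hw
        for lane in self.lanes:
            if lane.row0 < 0 or lane.row1 > h or lane.col0 < 0 or lane.col1 > w:
                raise ValueError(
                    f"lane {lane.lane_id} rectangle "
                    f"[{lane.row0}:{lane.row1}, {lane.col0}:{lane.col1}] "
                    f"outside frame of shape {frame_hw}; check lane calibration"
                )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame([vars(l) for l in self.lanes]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LaneMap":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(
                f"lane ROI file not found: {path} "
                "(expected CSV with columns lane_id,row0,row1,col0,col1,"
                "x_origin_px,px_per_mm)"
            )
        df = pd.read_csv(path)
        required = {"lane_id", "row0", "row1", "col0", "col1", "x_origin_px", "px_per_mm"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing lane ROI columns {sorted(missing)}")
        lanes = [
            LaneROI(
                lane_id=int(r.lane_id),
                row0=int(r.row0),
                row1=int(r.row1),
                col0=int(r.col0),
                col1=int(r.col1),
                x_origin_px=float(r.x_origin_px),
                px_per_mm=float(r.px_per_mm),
            )
            for r in df.itertuples()
        ]
        return cls(lanes=lanes)


def frame_shape(
    geometry: ArenaGeometry, margin_px: int = DEFAULT_MARGIN_PX
) -> tuple[int, int]:
    """(height, width) of a simulator camera frame for this geometry."""
    lane_h = max(1, round(geometry.lane_width_mm * geometry.camera_px_per_mm))
    lane_w = round(geometry.lane_length_mm * geometry.camera_px_per_mm) + 1
    height = 2 * margin_px + geometry.lane_count * (lane_h + 1) + 1
    width = 2 * margin_px + lane_w
    return height, width


def build_lane_map(
    geometry: ArenaGeometry, margin_px: int = DEFAULT_MARGIN_PX
) -> LaneMap:
    """Lane map matching the simulator's frame layout.

    Lane interiors are separated by 1 px boundary rows.  The detection
    rectangle extends ``margin_px`` past both lane ends horizontally so a
    blob centred exactly at a lane end keeps its full footprint inside the
    rectangle (an unbiased centroid at the boundary).
    """
    lane_h = max(1, round(geometry.lane_width_mm * geometry.camera_px_per_mm))
    lane_w = round(geometry.lane_length_mm * geometry.camera_px_per_mm) + 1
    x0 = margin_px
    lanes = []
    for i in range(geometry.lane_count):
        row0 = margin_px + 1 + i * (lane_h + 1)
        lanes.append(
            LaneROI(
                lane_id=i,
                row0=row0,
                row1=row0 + lane_h,
                col0=0,
                col1=2 * margin_px + lane_w,
                x_origin_px=float(x0),
                px_per_mm=geometry.camera_px_per_mm,
            )
        )
    return LaneMap(lanes=lanes)


def lane_boundary_rows(
    geometry: ArenaGeometry, margin_px: int = DEFAULT_MARGIN_PX
) -> Sequence[int]:
    """Row indices of the faint horizontal lane-boundary lines."""
    lane_h = max(1, round(geometry.lane_width_mm * geometry.camera_px_per_mm))
    return [margin_px + i * (lane_h + 1) for i in range(geometry.lane_count + 1)]
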