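"""Tracking chain: windowing, background subtraction, denoising, detection."""

import numpy as np
import pytest

from omr_assay.arena import ArenaGeometry, build_lane_map
from omr_assay.pipeline import trial_windows
from omr_assay.stimulus import default_schedule
from omr_assay.tracking import (
    FrameStack,
    denoise_and_polarize,
    detect_onset_positions,
    detect_positions,
    extract_analysis_window,
    subtract_background,
    track_window,
    trajectories_to_dataframe,
    trajectory_projection,
)


@pytest.fixture(scope="module")
def tracked_trial(small_sim, small_lanes):
    """First motion-phase window of the small simulation, fully tracked."""
    truth, stack = small_sim
    w = trial_windows(default_schedule(), truth.camera_fps, rounds=1)[0]
    raw = FrameStack(stack[w.onset_frame : w.onset_frame + 200], truth.camera_fps)
    onsets, trajectories, processed = track_window(raw, small_lanes)
    true_window = truth.positions_mm[:, w.onset_frame : w.onset_frame + 200]
    return raw, onsets, trajectories, processed, true_window


class TestWindow:
    def test_extracts_first_200_frames(self):
        stack = FrameStack(np.arange(600 * 4, dtype=np.uint8).reshape(600, 2, 2))
        win = extract_analysis_window(stack, 200)
        assert len(win) == 200
        assert np.array_equal(win.frames[0], stack.frames[0])

    def test_window_equal_to_stack_is_identity(self):
        stack = FrameStack(np.zeros((50, 2, 2), dtype=np.uint8))
        assert len(extract_analysis_window(stack, 50)) == 50

    def test_zero_window_rejected(self):
        stack = FrameStack(np.zeros((50, 2, 2), dtype=np.uint8))
        with pytest.raises(ValueError):
            extract_analysis_window(stack, 0)

    def test_short_stack_error_names_required_length(self):
        stack = FrameStack(np.zeros((100, 2, 2), dtype=np.uint8))
        with pytest.raises(ValueError, match="200"):
            extract_analysis_window(stack, 200)


class TestBackgroundSubtraction:
    def test_identical_frames_give_zero_stack(self):
        frames = np.full((5, 4, 4), 200, dtype=np.uint8)
        out = subtract_background(FrameStack(frames))
        assert out.frames.dtype == np.float32
        assert (out.frames == 0).all()

    def test_frame_zero_is_identically_zero(self, small_sim):
        _, stack = small_sim
        out = subtract_background(FrameStack(stack[:50]))
        assert (out.frames[0] == 0).all()

    def test_moving_blob_leaves_imprint_and_ghost(self):
        frames = np.full((2, 10, 20), 200, dtype=np.uint8)
        frames[0, 5, 3] = 50   # blob at x=3 in the background frame
        frames[1, 5, 15] = 50  # blob moved to x=15
        out = subtract_background(FrameStack(frames)).frames
        assert out[1, 5, 15] == -150  # imprint at current position
        assert out[1, 5, 3] == +150   # ghost at the frame-0 position
        assert (out[1] != 0).sum() == 2

    def test_translation_equivariance(self, rng):
        frames = rng.integers(0, 255, size=(6, 16, 24)).astype(np.uint8)
        shifted = np.roll(frames, shift=(3, 5), axis=(1, 2))
        a = subtract_background(FrameStack(frames)).frames
        b = subtract_background(FrameStack(shifted)).frames
        assert np.array_equal(np.roll(a, shift=(3, 5), axis=(1, 2)), b)


class TestDenoise:
    def test_single_pixel_impulse_removed(self):
        frames = np.zeros((1, 40, 40), dtype=np.float32)
        frames[0, 20, 20] = -200.0
        out = denoise_and_polarize(FrameStack(frames))
        assert np.abs(out.frames).max() == 0.0

    def test_large_disk_survives_with_center_preserved(self):
        yy, xx = np.mgrid[:60, :60]
        disk10 = (np.hypot(yy - 30, xx - 30) <= 10).astype(np.float32) * -150.0
        out = denoise_and_polarize(FrameStack(disk10[None]))
        assert out.frames[0, 30, 30] == pytest.approx(150.0)

    def test_constant_frame_maps_to_constant(self):
        out = denoise_and_polarize(FrameStack(np.zeros((2, 20, 20), dtype=np.float32)))
        assert (out.frames == 0).all()

    def test_polarity_flip_makes_larva_maximal(self):
        yy, xx = np.mgrid[:60, :60]
        frame = np.zeros((60, 60), dtype=np.float32)
        frame[np.hypot(yy - 30, xx - 15) <= 8] = -150.0  # larva imprint
        frame[np.hypot(yy - 30, xx - 45) <= 8] = +150.0  # ghost
        out = denoise_and_polarize(FrameStack(frame[None])).frames[0]
        assert out[30, 15] > 0  # larva now maximal
        assert out[30, 45] < 0  # ghost pushed negative


class TestDetection:
    def test_positions_within_half_pixel_of_truth(self, tracked_trial, small_geometry):
        _, _, trajectories, _, true_window = tracked_trial
        errs = []
        for i, traj in enumerate(trajectories):
            det = traj.detected
            assert det.mean() > 0.5
            errs.append(
                (traj.pos_mm[det] - true_window[i, det]) * small_geometry.camera_px_per_mm
            )
        rmse = np.sqrt(np.mean(np.concatenate(errs) ** 2))
        assert rmse <= 0.5

    def test_onset_positions_from_raw_first_frame(self, tracked_trial):
        raw, onsets, _, _, true_window = tracked_trial
        assert np.isfinite(onsets).all()
        assert np.abs(onsets - true_window[:, 0]).max() <= 0.5  # mm

    def test_constant_stack_yields_all_gaps(self, small_lanes, small_geometry):
        from omr_assay.arena import frame_shape

        h, w = frame_shape(small_geometry)
        stack = FrameStack(np.zeros((3, h, w), dtype=np.float32))
        trajs = detect_positions(stack, small_lanes)
        for t in trajs:
            assert not t.detected.any()
            assert np.isnan(t.pos_mm).all()

    def test_largest_blob_wins_over_debris(self, small_lanes, small_geometry):
        from omr_assay.arena import frame_shape

        h, w = frame_shape(small_geometry)
        frame = np.zeros((h, w), dtype=np.float32)
        lane = small_lanes[0]
        cy = int(lane.center_row)
        x_larva = int(lane.mm_to_px(60.0))
        x_debris = int(lane.mm_to_px(100.0))
        yy, xx = np.mgrid[:h, :w]
        frame[np.hypot(yy - cy, xx - x_larva) <= 4.5] = 150.0   # larva, ~60 px
        frame[np.hypot(yy - cy, xx - x_debris) <= 2.0] = 150.0  # debris, ~13 px
        trajs = detect_positions(FrameStack(frame[None]), small_lanes)
        assert trajs[0].detected[0]
        assert trajs[0].pos_mm[0] == pytest.approx(60.0, abs=0.5)

    def test_intensity_scale_invariance(self, small_lanes, small_geometry):
        from omr_assay.arena import frame_shape

        h, w = frame_shape(small_geometry)
        frame = np.zeros((h, w), dtype=np.float32)
        lane = small_lanes[1]
        cy = int(lane.center_row)
        x = int(lane.mm_to_px(80.0))
        yy, xx = np.mgrid[:h, :w]
        frame[np.hypot(yy - cy, xx - x) <= 4.5] = 150.0
        base = detect_positions(FrameStack(frame[None]), small_lanes)[1].pos_mm[0]
        for scale in (0.5, 2.0, 3.0):
            scaled = detect_positions(FrameStack((frame * scale)[None]), small_lanes,
                                      min_amplitude=10.0)[1].pos_mm[0]
            assert scaled == pytest.approx(base, abs=0.1)

    def test_interior_gaps_interpolated_leading_left_missing(self):
        from omr_assay.tracking import _interpolate_gaps

        pos = np.array([np.nan, 10.0, np.nan, np.nan, 16.0, np.nan])
        det = ~np.isnan(pos)
        filled, interp = _interpolate_gaps(pos, det)
        assert np.isnan(filled[0]) and np.isnan(filled[5])
        assert filled[2] == pytest.approx(12.0)
        assert filled[3] == pytest.approx(14.0)
        assert interp.tolist() == [False, False, True, True, False, False]

    def test_pipeline_determinism_bit_identical_tables(self, tracked_trial, small_lanes):
        raw, _, trajectories, _, _ = tracked_trial
        _, again, _ = track_window(raw, small_lanes)
        a = trajectories_to_dataframe(trajectories, raw.camera_fps)
        b = trajectories_to_dataframe(again, raw.camera_fps)
        assert a.equals(b)


class TestProjection:
    def test_projection_dimensions_match_frames(self, tracked_trial):
        _, _, _, processed, _ = tracked_trial
        img = trajectory_projection(processed)
        assert img.shape == processed.frame_shape + (3,)
        assert img.dtype == np.uint8

    def test_moving_blob_colors_by_time_along_lane(self):
        # a blob marching rightward: later (larger) column -> later time color
        h, w = 20, 120
        frames = np.zeros((30, h, w), dtype=np.float32)
        yy, xx = np.mgrid[:h, :w]
        for t in range(30):
            cx = 10 + 3 * t
            frames[t][np.hypot(yy - 10, xx - cx) <= 4] = 150.0
        img = trajectory_projection(FrameStack(frames))
        clipped = frames.max(axis=0)
        when = frames.argmax(axis=0)[clipped > 0]
        cols = np.mgrid[:h, :w][1][clipped > 0]
        assert np.corrcoef(cols, when)[0, 1] > 0.95
        assert img[:, :5].max() == 0  # untouched pixels stay black
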