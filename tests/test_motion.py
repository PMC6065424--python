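"""Tests for NCC, rigid tracking, ROI fallback and intensity series."""

import numpy as np
import pytest
from dataclasses import replace

from sff.errors import (
    DegenerateInputError,
    DegenerateWindowError,
    TrackingInfeasibleError,
)
from sff.motion import (
    RigidTransform,
    SearchBounds,
    ncc,
    roi_intensity_series,
    select_tracking_roi,
    track_roi,
    warp_to_reference,
)
from sff.phantom import PhantomConfig, generate_cine


def textured_frames(rng, n=3, shape=(64, 64)):
    base = rng.uniform(0, 1, shape)
    return np.stack([base] * n)


class TestNCC:
    def test_identical_windows(self, rng):
        w = rng.uniform(0, 1, (8, 8))
        assert ncc(w, w) == pytest.approx(1.0)

    def test_negated_window(self, rng):
        w = rng.uniform(0, 1, (8, 8))
        assert ncc(w, 2 * w.mean() - w) == pytest.approx(-1.0)

    def test_affine_intensity_invariance(self, rng):
        w = rng.uniform(0, 1, (10, 10))
        assert ncc(w, 1.7 * w + 0.3) == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_raises_degenerate_signal(self):
        with pytest.raises(DegenerateWindowError):
            ncc(np.full((5, 5), 0.5), np.full((5, 5), 0.5))


class TestRigidTransform:
    def test_inverse_round_trips_coordinates(self, rng):
        tf = RigidTransform(dx=2.3, dy=-1.7, theta=4.5)
        center = (31.5, 28.0)
        rows = rng.uniform(10, 50, 200)
        cols = rng.uniform(10, 50, 200)
        r1, c1 = tf.apply(rows, cols, center)
        r2, c2 = tf.inverse().apply(r1, c1, center)
        assert np.max(np.hypot(r2 - rows, c2 - cols)) <= 0.1

    def test_identity(self):
        tf = RigidTransform.identity()
        r, c = tf.apply(np.array([3.0]), np.array([4.0]), (0.0, 0.0))
        assert (r[0], c[0]) == (3.0, 4.0)


class TestTrackROI:
    @pytest.fixture()
    def roi(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[20:44, 20:44] = True
        return mask

    def test_static_frames_give_identity(self, rng, roi):
        frames = textured_frames(rng, n=4)
        tracked = track_roi(frames, roi, SearchBounds(max_shift=4, max_rot=1.0))
        for tf in tracked.transforms:
            assert (tf.dx, tf.dy, tf.theta) == (0.0, 0.0, 0.0)
        np.testing.assert_allclose(tracked.ncc_scores, 1.0, atol=1e-12)

    def test_known_integer_translation_recovered_exactly(self, rng, roi):
        base = rng.uniform(0, 1, (64, 64))
        moved = np.roll(base, shift=(3, -2), axis=(0, 1))
        tracked = track_roi(np.stack([base, moved]), roi, SearchBounds(max_shift=5, max_rot=0))
        tf = tracked.transforms[1]
        assert (tf.dy, tf.dx) == (3.0, -2.0)

    def test_known_rotation_recovered_within_grid_step(self):
        cfg = PhantomConfig(
            shape=(72, 72),
            n_frames=2,
            motion="fixed",
            motion_transforms=[
                RigidTransform.identity(),
                RigidTransform(dx=0.0, dy=0.0, theta=2.0),
            ],
            speckle_decorrelation=0.0,
            gain_jitter_std=0.0,
            seed=5,
        )
        run = generate_cine(cfg)
        roi = np.zeros((72, 72), dtype=bool)
        roi[16:56, 16:56] = True
        tracked = track_roi(run.frames, roi, SearchBounds(max_shift=3, max_rot=3, rot_step=0.5))
        assert abs(tracked.transforms[1].theta - 2.0) <= 0.5

    def test_best_ncc_never_decreases_when_truth_on_grid(self, rng, roi):
        """Adding the true transform to the search grid can only help."""
        base = rng.uniform(0, 1, (64, 64))
        moved = np.roll(base, shift=(0, 4), axis=(0, 1))
        frames = np.stack([base, moved])
        small = track_roi(frames, roi, SearchBounds(max_shift=2, max_rot=0))
        full = track_roi(frames, roi, SearchBounds(max_shift=5, max_rot=0))
        assert full.ncc_scores[1] >= small.ncc_scores[1] - 1e-12
        assert full.transforms[1].dx == 4.0

    def test_margin_and_size_preconditions(self, rng):
        frames = textured_frames(rng, n=2)
        edge_roi = np.zeros((64, 64), dtype=bool)
        edge_roi[0:10, 0:10] = True
        with pytest.raises(DegenerateInputError):
            track_roi(frames, edge_roi, SearchBounds(max_shift=8))
        with pytest.raises(DegenerateInputError):
            track_roi(frames[:1], edge_roi)


class TestSelectTrackingROI:
    def test_rich_primary_selected(self, rng):
        frames = textured_frames(rng)
        primary = np.zeros((64, 64), bool)
        primary[10:30, 10:30] = True
        mask, label = select_tracking_roi(frames, primary)
        assert label == "primary"
        np.testing.assert_array_equal(mask, primary)

    def test_flat_primary_falls_back_to_textured_alternative(self, rng):
        frames = textured_frames(rng)
        frames[:, 10:30, 10:30] = 0.5  # flatten the primary region
        primary = np.zeros((64, 64), bool)
        primary[10:30, 10:30] = True
        alt = np.zeros((64, 64), bool)
        alt[40:60, 40:60] = True
        mask, label = select_tracking_roi(frames, primary, (alt,))
        assert label == "alt_0"
        np.testing.assert_array_equal(mask, alt)

    def test_all_flat_is_infeasible(self):
        frames = np.full((2, 64, 64), 0.5)
        primary = np.zeros((64, 64), bool)
        primary[10:30, 10:30] = True
        with pytest.raises(TrackingInfeasibleError):
            select_tracking_roi(frames, primary)


class TestROIIntensitySeries:
    def _identity_tracked(self, frames, roi):
        return track_roi(frames, roi, SearchBounds(max_shift=1, max_rot=0))

    def test_constant_frames_normalize_to_zeros(self, rng):
        frames = np.full((3, 48, 48), 0.5) + 1e-4 * rng.standard_normal((3, 48, 48))
        frames[:] = frames[0]  # static but textured enough to track
        roi = np.zeros((48, 48), bool)
        roi[20:30, 20:30] = True
        tracked = self._identity_tracked(frames, roi)
        frames_const = np.full((3, 48, 48), 0.5)
        with pytest.warns(RuntimeWarning):
            series = roi_intensity_series(frames_const, tracked, roi)
        assert np.all(series.normalized == 0.0)

    def test_monotone_ramp_has_peak_at_last_frame(self, rng):
        base = rng.uniform(0.2, 0.4, (48, 48))
        frames = np.stack([np.clip(base + 0.05 * k, 0, 1) for k in range(6)])
        roi = np.zeros((48, 48), bool)
        roi[20:34, 20:34] = True
        tracked = self._identity_tracked(frames, roi)
        series = roi_intensity_series(frames, tracked, roi, times=np.arange(6.0))
        assert np.all(np.diff(series.normalized) >= -1e-12)
        assert series.normalized[-1] == pytest.approx(1.0)
        assert series.peak_intensity == pytest.approx(float(np.median(frames[-1][roi])))
        assert series.rise_index == int(np.argmax(series.normalized >= 0.9))

    def test_median_robust_to_ten_percent_outliers(self, rng):
        base = rng.uniform(0.3, 0.5, (48, 48))
        frames = np.stack([base, base.copy()])
        roi = np.zeros((48, 48), bool)
        roi[20:40, 20:40] = True
        idx = np.argwhere(roi)
        corrupt = idx[rng.choice(len(idx), size=len(idx) // 10, replace=False)]
        frames[1][corrupt[:, 0], corrupt[:, 1]] = 1.0
        tracked = self._identity_tracked(frames, roi)
        series = roi_intensity_series(frames, tracked, roi)
        # corrupting 10% of pixels moves the median only to the ~55th
        # percentile of the clean values (a ~0.01 shift here), while the mean
        # would jump by ~0.06
        assert series.median[1] == pytest.approx(series.median[0], abs=0.02)
        mean_shift = frames[1][roi].mean() - frames[0][roi].mean()
        assert abs(series.median[1] - series.median[0]) < 0.5 * mean_shift


class TestWarpToReference:
    def test_integer_shift_round_trip(self, rng):
        frame = rng.uniform(0, 1, (40, 40))
        tf = RigidTransform(dx=3.0, dy=-2.0)
        moved = warp_to_reference(frame, tf.inverse(), (19.5, 19.5))
        back = warp_to_reference(moved, tf, (19.5, 19.5))
        interior = (slice(6, 34), slice(6, 34))
        np.testing.assert_allclose(back[interior], frame[interior], atol=1e-9)
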