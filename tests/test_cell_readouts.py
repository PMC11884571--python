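"""Kinematics, fluorescence quantification and morphometrics."""

import math

import numpy as np
import pytest
from scipy import ndimage
from skimage.draw import disk

from stretchfield import synthgen
from stretchfield.cell_readouts import (
    ISOPERIMETRIC_BOUND,
    crop_segment,
    fluorescence_integral_series,
    mean_cell_speed,
    normalize_per_cell,
    register_to_landmark,
    rolling_ball_subtract,
    shape_metrics,
    track_labels,
)


class TestMeanCellSpeed:
    def test_static_stack_zero_speed(self, monolayer_static):
        phase, _, _ = monolayer_static
        s = mean_cell_speed(np.stack([phase[0], phase[0]]), dt_min=2.0)
        assert s.mean_speed[0] < 0.5

    def test_rigid_translation_hand_value(self, monolayer_static):
        # 1 µm shift at 0.5 µm/px in 2 min -> 30 µm/h
        phase, _, _ = monolayer_static
        shifted = ndimage.shift(phase[0], (0, 2.0), order=3, mode="nearest")
        s = mean_cell_speed(
            np.stack([phase[0], shifted]), dt_min=2.0, calibration=0.5
        )
        assert s.mean_speed[0] == pytest.approx(30.0, rel=0.1)

    def test_generator_drift_recovered(self):
        spec = synthgen.MonolayerSpec(
            n_cells=40, image_size=(384, 384), drift_speed=5.0, seed=6
        )
        schedule = synthgen.ActuationSchedule(
            [synthgen.ActuationFrame(120.0 * k, "relaxed") for k in range(6)]
        )
        phase, _, _ = synthgen.generate_monolayer_sequence(spec, schedule)
        s = mean_cell_speed(phase, dt_min=2.0, calibration=spec.calibration)
        assert np.mean(s.mean_speed) == pytest.approx(5.0, rel=0.1)

    def test_rejects_bad_inputs(self, monolayer_static):
        phase, _, _ = monolayer_static
        with pytest.raises(ValueError):
            mean_cell_speed(phase[:1])
        with pytest.raises(ValueError):
            mean_cell_speed(phase, dt_min=0.0)


class TestRollingBall:
    def test_constant_image_goes_to_zero(self):
        out = rolling_ball_subtract(np.full((256, 256), 80.0), radius=50)
        assert np.abs(out).max() < 1e-6

    def test_narrow_ridge_preserved(self):
        # bright 3-px ridges on flat background survive a 100 px disk
        img = np.full((256, 256), 50.0)
        img[:, 100:103] += 40.0
        out = rolling_ball_subtract(img, radius=100)
        assert out[:, 101].mean() == pytest.approx(40.0, rel=0.05)

    def test_smooth_gradient_removed(self):
        yy, xx = np.mgrid[0:256, 0:256]
        bg = 60.0 + 30.0 * xx / 255.0  # scale >> structure scale
        out = rolling_ball_subtract(bg, radius=50)
        assert out.max() <= 0.05 * 30.0 + 1.0

    def test_oversized_radius_warns(self):
        img = np.random.default_rng(0).uniform(10, 20, (64, 64))
        with pytest.warns(UserWarning):
            out = rolling_ball_subtract(img, radius=64)
        assert out.min() == 0.0


class TestFluorescenceIntegral:
    def test_first_frame_normalized_to_one(self, monolayer_static):
        _, fluor, _ = monolayer_static
        s = fluorescence_integral_series(fluor, radius=50)
        assert s.normalized[0] == 1.0

    def test_doubling_pixels_doubles_integral(self):
        img = np.zeros((128, 128))
        img[60:64, 60:64] = 10.0
        s = fluorescence_integral_series(np.stack([img, 2 * img]), radius=30)
        # tiny deviation allowed: the ball curvature lets the background
        # estimate rise slightly under the (scaled) feature
        assert s.integral[1] == pytest.approx(2 * s.integral[0], rel=0.01)

    def test_generator_ramp_recovered(self):
        amps = list(np.linspace(1.0, 1.5, 5))
        spec = synthgen.MonolayerSpec(
            n_cells=40, image_size=(384, 384), seed=8,
            junction_amplitude_schedule=amps,
        )
        schedule = synthgen.ActuationSchedule(
            [synthgen.ActuationFrame(60.0 * k, "relaxed") for k in range(5)]
        )
        _, fluor, _ = synthgen.generate_monolayer_sequence(spec, schedule)
        s = fluorescence_integral_series(fluor)
        assert s.normalized[-1] == pytest.approx(1.5, rel=0.1)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            fluorescence_integral_series(np.empty((0, 8, 8)))

    def test_crop_and_subtract_commute_on_background_free_frame(self, monolayer_static):
        # on a background-free junction image the integral over a shared ROI
        # is the same whether cropping precedes or follows subtraction
        _, fluor, _ = monolayer_static
        frame = fluor[0]
        a = rolling_ball_subtract(
            crop_segment(frame, 150.0, (192, 192), calibration=1.0), radius=60
        ).sum()
        b = crop_segment(
            rolling_ball_subtract(frame, radius=60), 150.0, (192, 192), calibration=1.0
        ).sum()
        assert a == pytest.approx(b, rel=0.02)


class TestRegistration:
    def test_aligned_stack_zero_offsets(self, monolayer_static):
        phase, _, _ = monolayer_static
        stack = np.stack([phase[0]] * 3)
        _, offsets = register_to_landmark(stack, (192, 192))
        assert offsets == [(0, 0)] * 3

    def test_known_shift_recovered_exactly(self, monolayer_static):
        phase, _, _ = monolayer_static
        moved = np.roll(np.roll(phase[0], -3, axis=0), 7, axis=1)
        reg, offsets = register_to_landmark(np.stack([phase[0], moved]), (192, 192))
        assert offsets[1] == (-7, 3)
        assert np.array_equal(reg[1], phase[0])

    def test_registration_commutes_with_crop(self, monolayer_static):
        phase, _, _ = monolayer_static
        moved = np.roll(phase[0], 4, axis=1)
        reg, _ = register_to_landmark(np.stack([phase[0], moved]), (192, 192))
        a = crop_segment(reg, 64.0, (192, 192), calibration=0.55)
        b = crop_segment(np.stack([phase[0], phase[0]]), 64.0, (192, 192), calibration=0.55)
        assert np.array_equal(a[1], b[1])


class TestCropSegment:
    def test_165um_at_055umpx_is_300px(self, monolayer_static):
        phase, _, _ = monolayer_static
        out = crop_segment(phase, 165.0, (192, 192), calibration=0.55)
        assert out.shape[-2:] == (300, 300)

    def test_full_size_crop_is_identity(self):
        img = np.arange(64.0 * 64).reshape(64, 64)
        out = crop_segment(img, 64.0, (32, 32), calibration=1.0)
        assert np.array_equal(out, img)

    def test_nested_crops(self):
        img = np.arange(128.0 * 128).reshape(128, 128)
        once = crop_segment(img, 40.0, (64, 64), calibration=1.0)
        twice = crop_segment(
            crop_segment(img, 80.0, (64, 64), calibration=1.0), 40.0, (40, 40), calibration=1.0
        )
        assert np.array_equal(once, twice)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            crop_segment(np.zeros((64, 64)), 60.0, (5, 5), calibration=1.0)


class TestShapeMetrics:
    def test_circle_closed_form(self):
        r = 10.0
        circ, sf = shape_metrics(math.pi * r**2, 2 * math.pi * r)
        assert circ == pytest.approx(1.0)
        assert sf == pytest.approx(ISOPERIMETRIC_BOUND)

    def test_unit_square(self):
        circ, sf = shape_metrics(1.0, 4.0)
        assert circ == pytest.approx(math.pi / 4)
        assert sf == pytest.approx(4.0)

    def test_scale_invariance(self):
        a = shape_metrics(7.3, 12.1)
        b = shape_metrics(7.3 * 9, 12.1 * 3)
        assert a == pytest.approx(b)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            shape_metrics(0.0, 5.0)

    def test_rasterized_disk_oracle(self):
        # Crofton perimeter calibration: disk of radius >= 30 px must give
        # circularity within 2% of 1 and shape factor within 1% of 2*sqrt(pi)
        mask = np.zeros((101, 101), dtype=np.int32)
        rr, cc = disk((50, 50), 35)
        mask[rr, cc] = 1
        tracks = track_labels(mask[None], calibration=1.0)
        (tr,) = tracks
        assert 0.98 <= tr.circularity[0] <= 1.02
        assert abs(tr.shape_factor[0] - ISOPERIMETRIC_BOUND) / ISOPERIMETRIC_BOUND < 0.01


class TestTracking:
    def _two_cell_mask(self):
        mask = np.zeros((64, 64), dtype=np.int32)
        rr, cc = disk((20, 20), 8)
        mask[rr, cc] = 1
        rr, cc = disk((44, 44), 10)
        mask[rr, cc] = 2
        return mask

    def test_static_masks_constant_tracks(self):
        mask = self._two_cell_mask()
        tracks = track_labels(np.stack([mask] * 3))
        assert len(tracks) == 2
        for tr in tracks:
            assert tr.frames == [0, 1, 2]
            assert len(set(tr.area_um2)) == 1

    def test_translation_tracked_continuously(self):
        mask = self._two_cell_mask()
        stack = np.stack([np.roll(mask, 2 * k, axis=1) for k in range(4)])
        tracks = track_labels(stack, gate_um=10.0)
        assert len(tracks) == 2
        for tr in tracks:
            assert tr.frames == [0, 1, 2, 3]
            xs = [c[0] for c in tr.centroids_um]
            steps = np.diff(xs)
            assert np.allclose(steps, 2.0, atol=0.2)

    def test_cell_exiting_fov_ends_track(self):
        mask = np.zeros((64, 64), dtype=np.int32)
        rr, cc = disk((32, 40), 8)
        mask[rr, cc] = 1
        stack = np.stack([np.roll(mask, 8 * k, axis=1) for k in range(4)])
        tracks = track_labels(stack, gate_um=20.0)
        (tr,) = tracks
        assert tr.frames[-1] < 3  # ends before the cell touches the border

    def test_labels_not_required_to_persist(self):
        # tracker matches by geometry, not generator label identity
        mask = self._two_cell_mask()
        relabeled = np.where(mask == 1, 5, np.where(mask == 2, 9, 0)).astype(np.int32)
        tracks = track_labels(np.stack([mask, relabeled]))
        assert sorted(len(t.frames) for t in tracks) == [2, 2]


class TestNormalizePerCell:
    def _track(self, cell_id, areas):
        from stretchfield.cell_readouts import CellTrack, _append

        tr = CellTrack(cell_id=cell_id)
        for t, a in enumerate(areas):
            _append(
                tr,
                t,
                {
                    "centroid_um": (0.0, 0.0),
                    "area_um2": a,
                    "perimeter_um": 4 * math.sqrt(a),
                    "touches_border": False,
                },
            )
        return tr

    def test_single_cell_sem_zero(self):
        res = normalize_per_cell([self._track(1, [10.0, 11.0])], n_frames=2)
        assert np.allclose(res["mean"], [1.0, 1.1])
        assert np.all(res["sem"] == 0.0)

    def test_identical_cells_sem_zero(self):
        tracks = [self._track(i, [10.0, 12.0]) for i in range(3)]
        res = normalize_per_cell(tracks, n_frames=2)
        assert np.allclose(res["sem"], 0.0)

    def test_missing_frame_zero_excluded(self):
        good = self._track(1, [10.0, 11.0])
        bad = self._track(2, [10.0, 11.0])
        bad.frames = [1, 2]
        res = normalize_per_cell([good, bad], n_frames=2)
        assert res["n_cells"] == 1

    def test_radial_stretch_area_oscillation(self):
        # alternating relaxed/stretched radial 5% -> area ratio (1.05)^2
        spec = synthgen.MonolayerSpec(n_cells=30, image_size=(256, 256), seed=12)
        deformation = synthgen.DeformationSpec(kind="radial", radial_strain=0.05)
        frames = []
        for k in range(2):
            frames.append(synthgen.ActuationFrame(20.0 * k + 3, "relaxed"))
            frames.append(
                synthgen.ActuationFrame(20.0 * k + 13, "stretched", deformation=deformation)
            )
        _, _, masks = synthgen.generate_monolayer_sequence(
            spec, synthgen.ActuationSchedule(frames)
        )
        tracks = track_labels(masks, calibration=0.55, gate_um=30.0)
        res = normalize_per_cell(tracks, n_frames=4, key="area_um2")
        ratio = res["mean"][1]
        assert ratio == pytest.approx(1.05**2, abs=0.02)
        assert res["mean"][2] == pytest.approx(1.0, abs=0.02)
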