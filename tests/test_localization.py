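"""Frame-to-localization chain: correction, detection, fitting,
merging, drift, filtering, reconstruction."""

import numpy as np
import pandas as pd
import pytest

from nanodomain.localization import (SMLMConfig, build_pixel_correction_mask,
                                     correct_frames, detect_candidates,
                                     drift_correct, filter_localizations,
                                     fit_spot, merge_localizations,
                                     reconstruct)
from nanodomain.simulate import CameraModel, FrameStack

CFG = SMLMConfig()


def stack_of(frames):
    return FrameStack(frames=np.asarray(frames, dtype=float),
                      camera=CameraModel(width=np.shape(frames)[2],
                                         height=np.shape(frames)[1]))


class TestPixelCorrection:
    def test_uniform_stack_empty_mask(self):
        stack = stack_of(np.full((5, 6, 6), 100.0))
        mask = build_pixel_correction_mask(stack, CFG)
        assert mask.n_flagged == 0
        assert np.all(mask.factors == 1.0)

    def test_hot_pixel_factor_is_neighbor_median_over_mean(self):
        img = np.full((5, 5), 100.0)
        img[2, 2] = 110.0
        mask = build_pixel_correction_mask(stack_of([img] * 4), CFG)
        assert mask.flagged == [(2, 2)]
        assert mask.factors[2, 2] == pytest.approx(100.0 / 110.0)

    def test_below_threshold_not_flagged(self):
        img = np.full((5, 5), 100.0)
        img[2, 2] = 102.0  # 2% <= 3%
        mask = build_pixel_correction_mask(stack_of([img] * 4), CFG)
        assert mask.n_flagged == 0

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        base = np.full((16, 16), 100.0)
        sens = np.ones((16, 16))
        sens[3, 4] = 1.2
        sens[10, 12] = 0.8
        frames = np.stack([base * sens + rng.normal(0, 0.5, (16, 16))
                           for _ in range(200)])
        stack = stack_of(frames)
        mask = build_pixel_correction_mask(stack, CFG)
        assert mask.n_flagged == 2
        corrected = correct_frames(stack, mask)
        mask2 = build_pixel_correction_mask(corrected, CFG)
        assert mask2.n_flagged == 0

    def test_small_sensor_error(self):
        with pytest.raises(ValueError):
            build_pixel_correction_mask(stack_of(np.ones((2, 2, 2))), CFG)


class TestCorrectFrames:
    def test_identity_with_empty_mask(self):
        stack = stack_of(np.full((3, 5, 5), 42.0))
        mask = build_pixel_correction_mask(stack, CFG)
        out = correct_frames(stack, mask, dark_counts=0.0)
        np.testing.assert_array_equal(out.frames, stack.frames)

    def test_flagged_pixel_rescaled(self):
        img = np.full((5, 5), 100.0)
        img[2, 2] = 110.0
        stack = stack_of([img] * 3)
        mask = build_pixel_correction_mask(stack, CFG)
        out = correct_frames(stack, mask, dark_counts=0.0)
        assert out.frames[0, 2, 2] == pytest.approx(100.0)

    def test_dark_subtraction_floored_at_zero(self):
        stack = stack_of(np.full((1, 5, 5), 90.0))
        mask = build_pixel_correction_mask(stack, CFG)
        out = correct_frames(stack, mask, dark_counts=100.0)
        assert np.all(out.frames == 0.0)

    def test_shape_mismatch_error(self):
        stack = stack_of(np.ones((1, 5, 5)))
        mask = build_pixel_correction_mask(stack, CFG)
        with pytest.raises(ValueError):
            correct_frames(stack_of(np.ones((1, 6, 6))), mask)


def render_spot(shape, x0, y0, sigma, n_photons, offset=0.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    g = np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma ** 2))
    return offset + n_photons / (2 * np.pi * sigma ** 2) * g


class TestDetection:
    def test_constant_frame_no_candidates(self):
        assert len(detect_candidates(np.full((32, 32), 7.0), CFG)) == 0

    def test_single_spot_detected_at_argmax(self):
        frame = render_spot((32, 32), 15.0, 11.0, 1.2, 2000.0, offset=10.0)
        cands = detect_candidates(frame, CFG)
        assert len(cands) == 1
        oracle = np.unravel_index(np.argmax(frame), frame.shape)
        assert tuple(cands[0]) == oracle

    def test_two_spots_detected(self):
        frame = (render_spot((40, 40), 10.0, 20.0, 1.2, 2000.0)
                 + render_spot((40, 40), 20.0, 20.0, 1.2, 2000.0) + 10.0)
        assert len(detect_candidates(frame, CFG)) == 2


class TestFitSpot:
    def test_noiseless_recovery(self):
        roi = render_spot((11, 11), 5.30, 4.70, 1.20, 1000.0, offset=5.0)
        rec = fit_spot(roi, CFG)
        assert rec["ok"]
        assert rec["x_px"] == pytest.approx(5.30, abs=1e-3)
        assert rec["y_px"] == pytest.approx(4.70, abs=1e-3)
        assert rec["sigma_px"] == pytest.approx(1.20, abs=1e-3)
        assert rec["photons"] == pytest.approx(1000.0, rel=0.01)

    def test_symmetric_roi_centered(self):
        roi = render_spot((9, 9), 4.0, 4.0, 1.5, 500.0)
        rec = fit_spot(roi, CFG)
        assert rec["x_px"] == pytest.approx(4.0, abs=1e-6)
        assert rec["y_px"] == pytest.approx(4.0, abs=1e-6)

    def test_poisson_noise_position_error_within_crlb_scale(self, rng):
        sigma, n = 1.3, 5000.0
        errs = []
        for _ in range(20):
            roi = rng.poisson(render_spot((11, 11), 5.2, 5.1, sigma, n,
                                          offset=10.0))
            rec = fit_spot(roi.astype(float), CFG)
            assert rec["ok"]
            errs.append(np.hypot(rec["x_px"] - 5.2, rec["y_px"] - 5.1))
        assert np.median(errs) < 3 * sigma / np.sqrt(n)

    def test_flat_roi_rejected(self):
        rec = fit_spot(np.full((7, 7), 3.0), CFG)
        assert not rec["ok"]
        assert rec["reason"] == "flat_roi"

    def test_even_roi_error(self):
        with pytest.raises(ValueError):
            fit_spot(np.ones((6, 6)), CFG)


class TestMerging:
    def test_single_localization_unchanged(self, loc_table_factory):
        t = loc_table_factory([[100.0, 100.0]])
        out = merge_localizations(t, CFG)
        assert len(out) == 1
        assert out["intensity_photon"].iloc[0] == 2000.0

    def test_gap_and_distance_within_limits_merged(self, loc_table_factory):
        t = loc_table_factory([[100.0, 100.0], [120.0, 100.0]],
                              frames=[1, 3])  # 1 off frame, 20 nm apart
        out = merge_localizations(t, CFG)
        assert len(out) == 1
        assert out["intensity_photon"].iloc[0] == 4000.0
        assert out["frame"].iloc[0] == 1
        assert out["x_nm"].iloc[0] == pytest.approx(110.0)

    def test_too_far_or_too_late_not_merged(self, loc_table_factory):
        far = loc_table_factory([[100.0, 100.0], [140.0, 100.0]],
                                frames=[1, 2])  # 40 nm apart
        assert len(merge_localizations(far, CFG)) == 2
        late = loc_table_factory([[100.0, 100.0], [110.0, 100.0]],
                                 frames=[1, 8])  # 6 off frames
        assert len(merge_localizations(late, CFG)) == 2

    def test_chain_spans_many_on_frames(self, loc_table_factory):
        # no on-frame limit: 10 consecutive detections collapse to one
        t = loc_table_factory([[100.0 + i, 100.0] for i in range(10)],
                              frames=list(range(1, 11)))
        assert len(merge_localizations(t, CFG)) == 1

    def test_count_and_intensity_conservation(self, rng, loc_table_factory):
        xy = rng.random((80, 2)) * 2000
        t = loc_table_factory(xy, frames=rng.integers(1, 40, 80))
        out = merge_localizations(t, CFG)
        assert len(out) <= len(t)
        assert out["intensity_photon"].sum() == pytest.approx(
            t["intensity_photon"].sum())


class TestDriftCorrection:
    def _clustered_table(self, n_frames):
        from nanodomain.simulate import (ClusterFieldSpec,
                                         field_to_localizations,
                                         generate_cluster_field)
        spec = ClusterFieldSpec(field_width=4000, field_height=4000, seed=3)
        t = field_to_localizations(generate_cluster_field(spec))
        rng = np.random.default_rng(4)
        t["frame"] = rng.integers(1, n_frames + 1, len(t))
        return t

    def test_too_few_frames_error(self, loc_table_factory):
        t = loc_table_factory([[0, 0]] * 4, frames=[1, 2, 3, 4])
        with pytest.raises(ValueError):
            drift_correct(t, CFG)

    def test_drift_free_shifts_near_zero(self):
        t = self._clustered_table(5000)
        _, trace = drift_correct(t, CFG)
        bin_nm = CFG.camera_pixel_nm / CFG.drift_magnification
        assert np.abs(trace[["drift_x_nm", "drift_y_nm"]].to_numpy()
                      ).max() <= bin_nm

    def test_linear_drift_recovered(self):
        t = self._clustered_table(5000)
        drifted = t.copy()
        drifted["x_nm"] = t["x_nm"] + 0.1 * t["frame"]
        drifted["y_nm"] = t["y_nm"] + 0.05 * t["frame"]
        corrected, trace = drift_correct(drifted, CFG)
        bin_nm = CFG.camera_pixel_nm / CFG.drift_magnification
        truth_x = 0.1 * (trace["frame_center"] - trace["frame_center"][0])
        truth_y = 0.05 * (trace["frame_center"] - trace["frame_center"][0])
        assert np.abs(trace["drift_x_nm"] - truth_x).max() < bin_nm
        assert np.abs(trace["drift_y_nm"] - truth_y).max() < bin_nm
        # correction is defined up to a global translation (bin-1 frame):
        # after removing the constant offset the residual spread is small
        rx = corrected["x_nm"] - t["x_nm"]
        ry = corrected["y_nm"] - t["y_nm"]
        resid = np.hypot(rx - rx.mean(), ry - ry.mean())
        assert resid.median() < bin_nm


class TestFilter:
    def test_bounds_enumeration(self, loc_table_factory):
        t = loc_table_factory(np.zeros((6, 2)))
        t.loc[0, "sigma_nm"] = 50.0          # below sigma range
        t.loc[1, "sigma_nm"] = 300.0         # above sigma range
        t.loc[2, "intensity_photon"] = 40_000.0
        t.loc[3, "uncertainty_nm"] = 35.0
        out = filter_localizations(t, CFG)
        assert len(out) == 2  # rows 4 and 5 survive
        t2 = loc_table_factory(np.zeros((1, 2)), sigma=100.0,
                               intensity=1000.0, uncertainty=10.0)
        assert len(filter_localizations(t2, CFG)) == 1

    def test_boundary_semantics(self, loc_table_factory):
        t = loc_table_factory(np.zeros((3, 2)))
        t.loc[0, "sigma_nm"] = 60.0       # inclusive bound: kept
        t.loc[1, "intensity_photon"] = 37_800.0  # strict: removed
        t.loc[2, "uncertainty_nm"] = 30.0        # strict: removed
        out = filter_localizations(t, CFG)
        assert list(out.index) == [0]

    def test_idempotent_projection(self, rng, loc_table_factory):
        t = loc_table_factory(rng.random((50, 2)) * 100)
        t["sigma_nm"] = rng.uniform(30, 320, 50)
        t["uncertainty_nm"] = rng.uniform(1, 40, 50)
        once = filter_localizations(t, CFG)
        twice = filter_localizations(once, CFG)
        pd.testing.assert_frame_equal(once, twice)
        assert set(once["sigma_nm"]).issubset(set(t["sigma_nm"]))

    def test_missing_column_error(self, loc_table_factory):
        t = loc_table_factory([[0, 0]]).drop(columns=["sigma_nm"])
        with pytest.raises(ValueError, match="sigma_nm"):
            filter_localizations(t, CFG)


class TestReconstruct:
    def test_single_localization_sum(self, loc_table_factory):
        t = loc_table_factory([[100.0, 100.0]])
        img = reconstruct(t, CFG)
        assert img.counts.sum() == 1

    def test_bin_size_from_magnification(self, loc_table_factory):
        img = reconstruct(loc_table_factory([[100.0, 100.0]]), CFG,
                          camera=CameraModel())
        assert img.bin_size_nm == pytest.approx(17.7)

    def test_out_of_bounds_dropped(self, rng, loc_table_factory):
        cam = CameraModel(width=32, height=32)
        fov = 32 * cam.pixel_size_nm
        xy = rng.random((1000, 2)) * fov
        xy[:10] += 2 * fov  # push 10 outside
        img = reconstruct(loc_table_factory(xy), CFG, camera=cam)
        assert img.counts.sum() == 990
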