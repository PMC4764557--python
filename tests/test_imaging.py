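"""Imaging pipeline: registration, dF/F, neuropil, maps, classification."""

import numpy as np
import pytest

from walltrack.ephys import TuningCurve
from walltrack.imaging import (
    RoiSet,
    classify_roi,
    dff,
    downsample_to_frames,
    extract_roi_traces,
    neuropil_correct,
    pixelwise_map,
    register_movie,
    rolling_baseline,
    smooth_tuning,
)
from walltrack.neurons import CalciumKernelParams, make_roi_grid, render_movie


def _textured_scene(seed=0, shape=(48, 48)):
    rng = np.random.default_rng(seed)
    return 100.0 * (1.0 + 0.2 * np.clip(rng.normal(0, 1, shape), -0.9, None))


class TestRegistration:
    def test_aligned_movie_has_zero_shifts(self):
        scene = _textured_scene()
        stack = np.stack([scene] * 4)
        motions, corrected = register_movie(stack, reference=scene)
        assert not motions.any()
        np.testing.assert_allclose(corrected, stack)

    def test_injected_shift_recovered_exactly(self):
        scene = _textured_scene()
        shifted = np.roll(scene, (3, -2), axis=(0, 1))
        motions, corrected = register_movie(np.stack([scene, shifted]), reference=scene)
        np.testing.assert_array_equal(motions, [[0, 0], [3, -2]])
        np.testing.assert_allclose(corrected[1], scene)

    def test_all_zero_frame_warns_and_keeps_position(self):
        scene = _textured_scene()
        stack = np.stack([scene, np.zeros_like(scene)])
        with pytest.warns(UserWarning, match="all zero"):
            motions, _ = register_movie(stack, reference=scene)
        assert motions[1].tolist() == [0, 0]

    def test_extraction_commutes_with_registration(self):
        # traces from a registered shifted movie match the unshifted movie
        labels = make_roi_grid((48, 48), 4, seed=1)
        rois = RoiSet.from_labels(labels)
        rng = np.random.default_rng(2)
        n = 50
        traces = np.abs(rng.normal(0.5, 0.3, (4, n)))
        shifts = rng.integers(-2, 3, (n, 2))
        shifts[0] = 0
        params = CalciumKernelParams()
        scene = _textured_scene(3)
        still = render_movie(rois.masks, traces, np.zeros(n), np.full((48, 48), 0.3),
                             np.zeros((n, 2), int), params, baseline_image=scene)
        moving = render_movie(rois.masks, traces, np.zeros(n), np.full((48, 48), 0.3),
                              shifts, params, baseline_image=scene)
        motions, corrected = register_movie(moving.stack, reference=moving.stack[0])
        np.testing.assert_array_equal(motions, shifts)
        roi_f_still, _ = extract_roi_traces(still.stack, rois)
        roi_f_reg, _ = extract_roi_traces(corrected, rois)
        np.testing.assert_allclose(roi_f_reg, roi_f_still, rtol=1e-6)


class TestRollingBaseline:
    def test_constant_trace_baseline_is_constant(self):
        F = np.full(100, 7.0)
        assert np.allclose(rolling_baseline(F, frame_rate=1.0), 7.0)

    def test_sparse_transients_do_not_move_baseline(self):
        F = np.full(400, 5.0)
        F[50:60] += 10.0
        F[200:210] += 10.0
        assert np.allclose(rolling_baseline(F, frame_rate=1.0), 5.0)

    def test_matches_brute_force_percentile_oracle(self):
        F = np.linspace(1.0, 1000.0, 300)
        fps, window_s = 2.0, 60.0
        F0 = rolling_baseline(F, frame_rate=fps, window_s=window_s)
        half = int(round(window_s * fps / 2))
        for i in [0, 1, 57, 150, 299]:
            window = np.sort(F[max(0, i - half): min(F.size, i + half + 1)])
            assert F0[i] == pytest.approx(np.percentile(window, 20))

    def test_nonpositive_baseline_raises(self):
        with pytest.raises(ValueError):
            rolling_baseline(np.full(50, -1.0), frame_rate=1.0)


class TestDff:
    def test_reference_values(self):
        F0 = np.full(3, 10.0)
        np.testing.assert_allclose(
            dff(np.array([10.0, 20.0, 5.0]), F0), [0.0, 1.0, -0.5]
        )

    def test_rejects_nonpositive_baseline(self):
        with pytest.raises(ValueError):
            dff(np.ones(3), np.zeros(3))

    def test_invariant_to_gain_of_raw_fluorescence(self):
        rng = np.random.default_rng(0)
        F = 50.0 + np.abs(rng.normal(0, 5, 300))
        out = dff(F, rolling_baseline(F, 1.0))
        out_scaled = dff(3.7 * F, rolling_baseline(3.7 * F, 1.0))
        np.testing.assert_allclose(out, out_scaled, atol=1e-12)


class TestExtraction:
    def test_uniform_frame_gives_constant_trace(self):
        labels = make_roi_grid((48, 48), 2, seed=0)
        rois = RoiSet.from_labels(labels)
        stack = np.full((5, 48, 48), 3.3)
        roi_f, ann_f = extract_roi_traces(stack, rois)
        assert np.allclose(roi_f, 3.3) and np.allclose(ann_f, 3.3)

    def test_single_pixel_mask_returns_pixel_series(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[10, 10] = 1
        rois = RoiSet.from_labels(labels)
        stack = np.random.default_rng(0).random((7, 20, 20))
        roi_f, _ = extract_roi_traces(stack, rois)
        np.testing.assert_allclose(roi_f[0], stack[:, 10, 10])

    def test_roi_signal_does_not_leak_into_annulus(self):
        labels = np.zeros((30, 30), dtype=int)
        labels[14:17, 14:17] = 1
        rois = RoiSet.from_labels(labels)
        stack = np.ones((4, 30, 30))
        boosted = stack.copy()
        boosted[:, rois.masks[0]] += 5.0
        _, ann_before = extract_roi_traces(stack, rois)
        _, ann_after = extract_roi_traces(boosted, rois)
        np.testing.assert_allclose(ann_before, ann_after)

    def test_empty_mask_raises(self):
        rois = RoiSet(masks=[np.zeros((10, 10), bool)], annuli=[np.ones((10, 10), bool)],
                      labels=["1"])
        with pytest.raises(ValueError, match="empty"):
            extract_roi_traces(np.ones((2, 10, 10)), rois)


class TestNeuropilCorrection:
    def test_zero_annulus_is_identity(self):
        roi = np.array([0.1, 0.5, 0.2])
        np.testing.assert_allclose(neuropil_correct(roi, np.zeros(3)), roi)

    def test_equal_traces_cancel_at_unit_coefficient(self):
        roi = np.array([0.1, 0.5, 0.2])
        assert not neuropil_correct(roi, roi, coefficient=1.0).any()

    def test_shared_field_removed_in_rendered_movie(self):
        # somatic trace recovered to < 5% RMS despite neuropil contamination
        labels = make_roi_grid((48, 48), 1, seed=0)
        rois = RoiSet.from_labels(labels)
        rng = np.random.default_rng(4)
        n = 600
        somatic = np.zeros(n)
        for s in rng.integers(0, n - 15, 12):
            somatic[s : s + 12] += np.exp(-np.arange(12) / 4.0)
        neuropil = 0.3 * np.abs(np.convolve(rng.normal(0, 1, n), np.ones(9) / 9, "same"))
        movie = render_movie(
            rois.masks, somatic[None, :], neuropil, np.full((48, 48), 1.0),
            np.zeros((n, 2), int), CalciumKernelParams(),
        )
        roi_f, ann_f = extract_roi_traces(movie.stack, rois)
        roi_d = dff(roi_f[0], rolling_baseline(roi_f[0], 7.0))
        ann_d = dff(ann_f[0], rolling_baseline(ann_f[0], 7.0))
        corrected = neuropil_correct(roi_d, ann_d)
        rms = np.sqrt(np.mean((corrected - somatic) ** 2))
        assert rms < 0.05 * max(1.0, somatic.max())


class TestPixelwiseMap:
    def test_indicator_pixel_maps_to_its_bin_with_full_r2(self):
        n = 120
        u = np.tile(np.array([5.0, 11.0, 17.0, 23.0]), n // 4)
        stack = np.zeros((n, 2, 2))
        stack[:, 0, 0] = (np.floor(u / 3) == 3).astype(float)  # bin [9,12)
        stack[:, 1, 1] = np.linspace(0, 1, n)  # unrelated drift
        m = pixelwise_map(stack, u, np.ones(n, bool))
        assert m.preferred[0, 0] == pytest.approx(10.5)
        assert m.r2[0, 0] == pytest.approx(1.0)

    def test_constant_pixel_has_zero_r2(self):
        n = 60
        u = np.tile(np.array([5.0, 11.0]), n // 2)
        stack = np.full((n, 1, 1), 2.0)
        m = pixelwise_map(stack, u, np.ones(n, bool))
        assert m.r2[0, 0] == 0.0

    def test_noise_pixel_r2_below_permutation_null_tail(self):
        rng = np.random.default_rng(0)
        n = 500
        u = rng.uniform(4, 34, n)
        trace = rng.normal(0, 1, n)
        stack = trace.reshape(n, 1, 1)
        m = pixelwise_map(stack, u, np.ones(n, bool))
        null = []
        for _ in range(200):
            perm = rng.permutation(n)
            null.append(pixelwise_map(stack[perm], u, np.ones(n, bool)).r2[0, 0])
        assert m.r2[0, 0] <= np.quantile(null, 0.99)

    def test_r2_matches_squared_correlation_with_prediction(self):
        rng = np.random.default_rng(1)
        n = 400
        u = rng.uniform(4, 34, n)
        stack = rng.normal(0, 1, (n, 3, 3))
        stack[:, 1, 1] += 2.0 * np.exp(-0.5 * ((u - 15) / 4) ** 2)
        m = pixelwise_map(stack, u, np.ones(n, bool))
        bins = np.floor(u / 3.0).astype(int)
        for (i, j) in [(1, 1), (0, 2)]:
            trace = stack[:, i, j]
            pred = np.zeros(n)
            for b in np.unique(bins):
                pred[bins == b] = trace[bins == b].mean()
            r = np.corrcoef(trace, pred)[0, 1]
            assert m.r2[i, j] == pytest.approx(r**2, abs=1e-9)

    def test_requires_two_occupied_bins(self):
        with pytest.raises(ValueError):
            pixelwise_map(np.ones((10, 1, 1)), np.full(10, 5.0), np.ones(10, bool))


class TestClassification:
    @staticmethod
    def _curve(values):
        values = np.asarray(values, float)
        return TuningCurve(
            bin_centers=(np.arange(values.size) + 0.5) * 3.0,
            mean=values,
            se=np.zeros_like(values),
            n_trials=np.full(values.size, 10),
        )

    def test_silent_roi_is_inactive(self):
        cls = classify_roi(np.zeros(100), self._curve([0, 0, 0]), p_value=1.0)
        assert cls.status == "inactive"

    def test_active_but_untuned(self):
        trace = np.zeros(100)
        trace[80:] = 1.5
        cls = classify_roi(trace, self._curve([0.5, 0.5, 0.5]), p_value=0.5)
        assert cls.status == "active_untuned"
        assert cls.q90 > 1.0

    def test_tuned_takes_precedence(self):
        trace = np.zeros(100)
        trace[80:] = 1.5
        cls = classify_roi(trace, self._curve([0.1, 0.7, 0.1]), p_value=0.01)
        assert cls.status == "tuned"

    def test_small_range_blocks_tuned_call(self):
        cls = classify_roi(np.zeros(100), self._curve([0.1, 0.3, 0.1]), p_value=0.001)
        assert cls.status == "inactive"


class TestSmoothing:
    @staticmethod
    def _gaussian_curve(se_value=0.05):
        x = (np.arange(12) + 0.5) * 3.0
        mean = 0.2 + 1.0 * np.exp(-0.5 * ((x - 18) / 6.0) ** 2)
        return TuningCurve(
            bin_centers=x, mean=mean, se=np.full(12, se_value), n_trials=np.full(12, 10)
        )

    def test_flat_curve_unchanged(self):
        x = (np.arange(10) + 0.5) * 3.0
        curve = TuningCurve(bin_centers=x, mean=np.full(10, 0.4), se=np.full(10, 0.05),
                            n_trials=np.full(10, 10))
        smoothed = smooth_tuning(curve)
        np.testing.assert_allclose(smoothed.mean, 0.4, atol=1e-9)

    def test_smooth_curve_changes_less_than_se(self):
        curve = self._gaussian_curve()
        smoothed = smooth_tuning(curve)
        assert np.all(np.abs(smoothed.mean - curve.mean) < curve.se)

    def test_mean_response_preserved(self):
        curve = self._gaussian_curve()
        smoothed = smooth_tuning(curve)
        assert smoothed.mean.mean() == pytest.approx(curve.mean.mean(), rel=0.01)

    def test_too_few_bins_returns_input_with_warning(self):
        x = (np.arange(3) + 0.5) * 3.0
        curve = TuningCurve(bin_centers=x, mean=np.array([1.0, 2.0, 1.0]),
                            se=np.zeros(3), n_trials=np.full(3, 5))
        with pytest.warns(UserWarning):
            smoothed = smooth_tuning(curve)
        np.testing.assert_allclose(smoothed.mean, curve.mean)


def test_downsample_to_frames_is_within_frame_mean():
    t = np.arange(0, 1.0, 0.1)
    values = np.arange(10, dtype=float)
    frame_times = np.array([0.0, 0.5])
    out = downsample_to_frames(values, t, frame_times, frame_rate=2.0)
    np.testing.assert_allclose(out, [np.mean([0, 1, 2, 3, 4]), np.mean([5, 6, 7, 8, 9])])
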