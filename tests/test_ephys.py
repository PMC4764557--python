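"""Spike-train tuning curves, significance testing, and the index family."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from walltrack.ephys import (
    TuningCurve,
    anova_tuning_test,
    baseline_response,
    bin_spike_rate,
    direction_summary,
    distance_tuning,
    laterality_index,
    movement_windows,
    open_closed_index,
    per_trial_bin_means,
    speed_gain_index,
    speed_tuning,
    split_trials_by_speed,
    tuning_summary,
)
from walltrack.neurons import NeuronModel, generate_spikes, rate_from_behavior


def _curve(values, bin_width=3.0, baseline=None, se=None):
    values = np.asarray(values, dtype=float)
    return TuningCurve(
        bin_centers=(np.arange(values.size) + 0.5) * bin_width,
        mean=values,
        se=np.zeros_like(values) if se is None else np.asarray(se, float),
        n_trials=np.full(values.size, 10),
        bin_width=bin_width,
        baseline=baseline,
    )


class TestBinSpikeRate:
    def test_single_spike_gives_500_hz_bin(self):
        rate, centers = bin_spike_rate(np.array([0.0105]), 0.002, 0.0, 0.01 * 2)
        assert rate[5] == pytest.approx(500.0)
        assert rate.sum() == pytest.approx(500.0)

    def test_empty_train_is_all_zero(self):
        rate, _ = bin_spike_rate(np.array([]), 0.002, 0.0, 1.0)
        assert rate.size == 500 and not rate.any()

    def test_rate_integral_conserves_spike_count(self):
        spikes = np.sort(np.random.default_rng(0).uniform(0, 10, 137))
        rate, _ = bin_spike_rate(spikes, 0.002, 0.0, 10.0)
        assert rate.sum() * 0.002 == pytest.approx(137)


class TestDistanceTuning:
    def test_constant_rate_gives_flat_curve_with_zero_se(self, open_loop_session):
        beh = open_loop_session
        rate = np.full(len(beh), 7.0)
        curve = distance_tuning(
            rate, beh["u_right"], beh["v"], beh["trial_id"]
        )
        d = curve.defined
        assert d.any()
        assert np.allclose(curve.mean[d], 7.0)
        assert np.allclose(curve.se[d], 0.0)

    def test_unimodal_neuron_peak_recovered_within_one_bin(self, open_loop_session):
        beh = open_loop_session
        model = NeuronModel(kind="unimodal", baseline=2.0, amplitude=12.0,
                            preferred=15.0, width=5.0)
        rate = rate_from_behavior(model, beh)
        spikes = generate_spikes(rate, 0.002, seed=11)
        binned, _ = bin_spike_rate(spikes, 0.002, 0.0, len(beh) * 0.002)
        curve = distance_tuning(
            binned[: len(beh)], beh["u_right"], beh["v"], beh["trial_id"]
        )
        peak_at = curve.bin_centers[np.nanargmax(curve.mean)]
        assert abs(peak_at - 15.0) <= 3.0

    def test_invariant_to_trial_relabelling(self, open_loop_session):
        beh = open_loop_session
        rng = np.random.default_rng(0)
        rate = rng.poisson(0.02, len(beh)) / 0.002
        ids = beh["trial_id"].to_numpy()
        perm = rng.permutation(ids.max() + 1)
        curve_a = distance_tuning(rate, beh["u_right"], beh["v"], ids)
        curve_b = distance_tuning(rate, beh["u_right"], beh["v"], perm[ids])
        np.testing.assert_allclose(curve_a.mean, curve_b.mean, equal_nan=True)

    def test_requires_running_trials(self, open_loop_session):
        beh = open_loop_session
        slow_v = np.full(len(beh), 1.0)
        with pytest.raises(ValueError, match="mean speed"):
            distance_tuning(np.zeros(len(beh)), beh["u_right"], slow_v, beh["trial_id"])


class TestAnova:
    def test_identical_groups_give_p_one(self):
        per_trial = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        assert anova_tuning_test(per_trial) == 1.0

    def test_separated_constant_groups_give_p_zero(self):
        per_trial = np.array([[0.0, 10.0], [0.0, 10.0], [0.0, 10.0]])
        assert anova_tuning_test(per_trial) == 0.0

    def test_degenerate_constant_input_gives_p_one(self):
        assert anova_tuning_test(np.full((5, 4), 2.0)) == 1.0

    def test_requires_two_populated_bins(self):
        with pytest.raises(ValueError):
            anova_tuning_test(np.array([[1.0, np.nan], [2.0, np.nan]]))

    def test_strong_tuning_detected(self, open_loop_session):
        beh = open_loop_session
        model = NeuronModel(kind="unimodal", baseline=1.0, amplitude=15.0, preferred=12.0)
        rate = rate_from_behavior(model, beh)
        spikes = generate_spikes(rate, 0.002, seed=2)
        binned, _ = bin_spike_rate(spikes, 0.002, 0.0, len(beh) * 0.002)
        curve = distance_tuning(binned[: len(beh)], beh["u_right"], beh["v"], beh["trial_id"])
        assert anova_tuning_test(curve.per_trial) < 1e-4


class TestTuningSummary:
    def test_purely_activated_unit_has_modulation_one(self):
        s = tuning_summary(_curve([5, 10, 5]), baseline=5.0)
        assert (s.activation, s.suppression, s.modulation) == (5.0, 0.0, 1.0)

    def test_purely_suppressed_unit_has_modulation_minus_one(self):
        s = tuning_summary(_curve([5, 0, 5]), baseline=5.0)
        assert (s.activation, s.suppression, s.modulation) == (0.0, 5.0, -1.0)

    def test_balanced_mixed_unit_has_modulation_zero(self):
        s = tuning_summary(_curve([2, 5, 8]), baseline=5.0)
        assert s.activation == s.suppression == 3.0
        assert s.modulation == 0.0

    def test_flat_curve_modulation_undefined(self):
        s = tuning_summary(_curve([5, 5, 5]), baseline=5.0)
        assert np.isnan(s.modulation)

    def test_missing_baseline_raises(self):
        with pytest.raises(ValueError, match="baseline"):
            tuning_summary(_curve([1, 2, 3]))


def test_baseline_response_uses_out_of_reach_running_epochs():
    rate = np.array([10.0, 10.0, 4.0, 4.0, 6.0])
    u = np.array([35.0, 35.0, 10.0, 35.0, 40.0])
    run = np.array([True, True, True, False, True])
    assert baseline_response(rate, u, run, out_of_reach=30.0) == pytest.approx((10 + 10 + 6) / 3)
    with pytest.raises(ValueError):
        baseline_response(rate, u, np.zeros(5, bool))


class TestDirection:
    @staticmethod
    def _rate_with_windows(towards_active, away_active):
        dt = 0.002
        t = np.arange(0, 6.0, dt)
        rate = np.zeros_like(t)
        towards = [(1.0, 2.0)]
        away = [(4.0, 5.0)]
        if towards_active:
            rate[(t >= 1.0) & (t < 1.5)] = 4.0
        if away_active:
            rate[(t >= 4.0) & (t < 4.5)] = 4.0
        return rate, t, towards, away

    def test_towards_only_unit_scores_one(self):
        rate, t, tw, aw = self._rate_with_windows(True, False)
        assert direction_summary(rate, t, tw, aw).index == 1.0

    def test_away_only_unit_scores_minus_one(self):
        rate, t, tw, aw = self._rate_with_windows(False, True)
        assert direction_summary(rate, t, tw, aw).index == -1.0

    def test_symmetric_unit_scores_zero(self):
        rate, t, tw, aw = self._rate_with_windows(True, True)
        assert direction_summary(rate, t, tw, aw).index == 0.0

    def test_missing_epochs_raise(self):
        rate, t, tw, _ = self._rate_with_windows(True, False)
        with pytest.raises(ValueError):
            direction_summary(rate, t, tw, [])

    def test_movement_windows_found_in_open_loop_session(self, open_loop_session):
        towards, away = movement_windows(open_loop_session)
        assert len(towards) > 10 and len(away) > 10
        # move-in windows last ~1 s under the 4-s schedule
        for start, end in towards[:5]:
            assert end - start == pytest.approx(1.0, abs=0.1)


class TestComparisonIndices:
    def test_laterality_limits(self):
        modulated = _curve([2, 7, 2])
        flat = _curve([2, 2, 2])
        assert laterality_index(modulated, flat).value == 1.0
        assert laterality_index(flat, modulated).value == -1.0
        assert laterality_index(modulated, modulated).value == 0.0
        assert np.isnan(laterality_index(flat, flat).value)

    def test_open_closed_equal_means_give_zero(self):
        u = np.linspace(5, 25, 100)
        rate = np.full(100, 6.0)
        idx = open_closed_index(rate, u, rate, u)
        assert idx.value == 0.0

    def test_open_closed_silent_closed_gives_one(self):
        u = np.linspace(5, 25, 100)
        idx = open_closed_index(np.full(100, 6.0), u, np.zeros(100), u)
        assert idx.value == 1.0

    def test_open_closed_antisymmetric(self):
        rng = np.random.default_rng(0)
        u = np.linspace(5, 25, 200)
        a, b = rng.poisson(5, 200).astype(float), rng.poisson(9, 200).astype(float)
        assert open_closed_index(a, u, b, u).value == pytest.approx(
            -open_closed_index(b, u, a, u).value
        )

    def test_speed_gain_recovers_multiplicative_scaling(self):
        slow = _curve([2, 5, 9, 5])
        assert speed_gain_index(_curve([2, 5, 9, 5]), slow).value == pytest.approx(0.0)
        fast2 = _curve([4, 10, 18, 10])
        assert speed_gain_index(fast2, slow).value == pytest.approx(np.log(2))
        half = _curve([1, 2.5, 4.5, 2.5])
        assert speed_gain_index(half, slow).value == pytest.approx(-np.log(2))

    def test_speed_gain_undefined_for_silent_slow_curve(self):
        assert np.isnan(speed_gain_index(_curve([1, 2, 3]), _curve([0, 0, 0])).value)

    @given(
        a=st.floats(0.0, 100.0),
        b=st.floats(0.0, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_ratio_indices_bounded_and_antisymmetric(self, a, b):
        ca, cb = _curve([0.0, a]), _curve([0.0, b])
        ab = laterality_index(ca, cb).value
        ba = laterality_index(cb, ca).value
        if not np.isnan(ab):
            assert -1.0 <= ab <= 1.0
            assert ab == pytest.approx(-ba)


class TestSpeedTuning:
    @staticmethod
    def _session(rng, slope=0.0, n_trials=30, samples=200):
        v_trial = rng.uniform(5.0, 30.0, n_trials)
        v = np.repeat(v_trial, samples)
        tid = np.repeat(np.arange(n_trials), samples)
        lam = 5.0 * (1 + slope * v) * 0.002
        response = rng.poisson(lam) / 0.002
        return response, v, tid

    def test_empty_out_of_reach_mask_raises(self):
        rng = np.random.default_rng(0)
        response, v, tid = self._session(rng)
        with pytest.raises(ValueError):
            speed_tuning(response, v, tid, np.zeros(v.size, bool))

    def test_speed_dependent_unit_detected(self):
        # ~2 s of out-of-reach samples per trial, as in far-hold trials
        rng = np.random.default_rng(1)
        response, v, tid = self._session(rng, slope=0.15, samples=1000)
        curve, p = speed_tuning(response, v, tid, np.ones(v.size, bool))
        assert p < 0.05
        d = curve.defined
        assert curve.mean[d][-1] > curve.mean[d][0]

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            response, v, tid = self._session(rng, slope=0.0, samples=50)
            _, p = speed_tuning(response, v, tid, np.ones(v.size, bool))
            rejections += p < 0.05
        # binomial 99.9% interval around 0.05 for 200 sims
        assert 1 <= rejections <= 21


def test_split_trials_by_speed_median():
    v = np.repeat([1.0, 10.0, 20.0, 30.0, 40.0], 10)
    tid = np.repeat(np.arange(5), 10)
    fast, slow = split_trials_by_speed(v, tid)
    assert set(fast) == {3, 4}
    assert set(slow) == {1, 2}  # trial 0 not running


def test_per_trial_bin_means_against_manual_grouping():
    u = np.array([4.0, 5.0, 10.0, 11.0, 4.5, 10.5])
    resp = np.array([1.0, 3.0, 5.0, 7.0, 10.0, 20.0])
    tid = np.array([0, 0, 0, 0, 1, 1])
    per_trial, centers, ids = per_trial_bin_means(resp, u, tid, bin_width=3.0)
    assert centers.tolist() == [4.5, 7.5, 10.5]
    np.testing.assert_allclose(per_trial[0], [2.0, np.nan, 6.0])
    np.testing.assert_allclose(per_trial[1], [10.0, np.nan, 20.0])
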