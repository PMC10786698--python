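"""ΔF extraction, event detection, alternation index, frequency, total signal."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinecpg import (DegenerateInputError, ParameterError,
                      UndefinedStatisticError, neural, synthetic as syn)
from spinecpg.neural import EventTrain, ManualBaseline, RollingPercentileBaseline


class TestComputeDff:
    def test_identity_when_trace_equals_baseline(self):
        trace = np.full(100, 7.0)
        np.testing.assert_array_equal(
            neural.compute_dff(trace, ManualBaseline(7.0)), 0.0)

    def test_constant_shift(self):
        trace = np.full(100, 10.0)
        np.testing.assert_array_equal(
            neural.compute_dff(trace, ManualBaseline(7.0)), 3.0)

    def test_rolling_percentile_recovers_transient_peak(self):
        params = syn.CPGSimParams(seed=6, event_rate=0.05, duration=120.0,
                                  amplitude_mean=10.0, amplitude_cv=0.0,
                                  noise_sd=0.0, baseline_level=100.0,
                                  baseline_drift_slope=0.0, n_rois_per_side=1)
        traces, truth = syn.simulate_bilateral_traces(params)
        times = truth.times
        # only isolated transients: neighbours' tails would add to the peak
        isolated = [(t, s) for t, s in zip(times, truth.side_sequence)
                    if np.sum(np.abs(times - t) < 8.0) == 1 and t < 115.0]
        assert isolated
        for t, side in isolated:
            dff = neural.compute_dff(traces.side_sum(side), fps=traces.fps)
            lo = int(t * traces.fps)
            peak = dff[lo:lo + int(2.0 * traces.fps)].max()
            assert peak == pytest.approx(10.0, rel=0.05)

    def test_window_longer_than_recording_rejected(self):
        with pytest.raises(ParameterError):
            neural.compute_dff(np.zeros(10), RollingPercentileBaseline(10, 20.0),
                               fps=10.0)

    def test_empty_trace_rejected(self):
        with pytest.raises(DegenerateInputError):
            neural.compute_dff(np.array([]), ManualBaseline(0.0))


class TestRelativeIntensity:
    def test_direct_arithmetic(self):
        np.testing.assert_allclose(neural.relative_intensity([1.0, 3.0]),
                                   [50.0, 150.0])

    def test_constant_maps_to_100(self):
        np.testing.assert_allclose(neural.relative_intensity(np.full(5, 2.5)), 100.0)

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_output_mean_is_always_100(self, values):
        dff = np.asarray(values)
        m = dff.mean()
        if m == 0 or abs(m) < 1e-12 * max(1.0, np.abs(dff).max()):
            with pytest.raises(DegenerateInputError):
                neural.relative_intensity(dff)
        else:
            out = neural.relative_intensity(dff)
            assert out.mean() == pytest.approx(100.0, rel=1e-9)


class TestDetectEvents:
    def test_flat_trace_has_no_events(self):
        train = neural.detect_events(np.zeros(600), fps=10.0, side="left")
        assert len(train) == 0

    def test_refractory_rule_merges_close_peaks(self):
        dff = np.zeros(100)
        dff[50] = 10.0
        dff[55] = 8.0  # 0.05 s apart at 100 fps, inside the refractory window
        train = neural.detect_events(dff, fps=100.0, side="left",
                                     min_interval_s=0.5)
        assert len(train) == 1
        assert train.events.iloc[0]["peak_amplitude"] == pytest.approx(10.0)

    def test_strong_events_recovered_with_onset_accuracy(self):
        params = syn.CPGSimParams(seed=8, event_rate=0.2, duration=120.0,
                                  amplitude_mean=20.0, amplitude_cv=0.0,
                                  noise_sd=2.0, n_rois_per_side=1)
        traces, truth = syn.simulate_bilateral_traces(params)
        trains = neural.detect_side_events(traces)
        # one frame of detector latency plus up to half a frame from
        # rendering continuous ground-truth onsets on the frame grid; events
        # whose transient is cut off by the end of the recording are excluded
        for _, ev in truth.events.iterrows():
            if ev["onset_time_s"] > params.duration - 2.0:
                continue
            det = trains[ev["side"]].times
            assert np.min(np.abs(det - ev["onset_time_s"])) <= 1.5 / params.fps + 1e-9

    def test_constant_offset_invariance_with_percentile_baseline(self):
        params = syn.CPGSimParams(seed=9, duration=60.0, n_rois_per_side=1)
        traces, _ = syn.simulate_bilateral_traces(params)
        raw = traces.side_sum("left")
        d0 = neural.compute_dff(raw, fps=traces.fps)
        d1 = neural.compute_dff(raw + 500.0, fps=traces.fps)
        t0 = neural.detect_events(d0, traces.fps, "left")
        t1 = neural.detect_events(d1, traces.fps, "left")
        np.testing.assert_allclose(t0.times, t1.times)

    def test_non_finite_rejected(self):
        with pytest.raises(DegenerateInputError):
            neural.detect_events(np.array([0.0, np.nan, 0.0]), 10.0, "left")


class TestAlternationIndex:
    @pytest.mark.parametrize("sides, expected", [
        (["left", "right", "left", "right", "left"], 1.0),
        (["left", "left", "left", "left"], 0.0),
        (["left", "left", "right", "left", "right"], 0.75),
    ])
    def test_hand_enumerated_sequences(self, sides, expected):
        train = EventTrain.from_records(
            [(float(i), s, 1.0, None) for i, s in enumerate(sides)])
        assert neural.alternation_index(train) == expected

    def test_bilateral_pairs_count_as_not_opposite(self):
        train = EventTrain.from_records(
            [(0.0, "left", 1.0, None), (1.0, "bilateral", 1.0, None),
             (2.0, "right", 1.0, None)])
        assert neural.alternation_index(train) == 0.0

    def test_single_event_undefined(self):
        train = EventTrain.from_records([(0.0, "left", 1.0, None)])
        with pytest.raises(UndefinedStatisticError):
            neural.alternation_index(train)

    @given(st.lists(st.sampled_from(["left", "right", "bilateral"]),
                    min_size=2, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_one_iff_strict_alternation(self, sides):
        train = EventTrain.from_records(
            [(float(i), s, 1.0, None) for i, s in enumerate(sides)])
        idx = neural.alternation_index(train)
        assert 0.0 <= idx <= 1.0
        strictly_alternating = ("bilateral" not in sides and
                                all(a != b for a, b in zip(sides, sides[1:])))
        assert (idx == 1.0) == strictly_alternating

    def test_iid_equiprobable_sides_average_one_half(self):
        rng = np.random.default_rng(77)
        sides = rng.choice(["left", "right"], size=10_000)
        train = EventTrain.from_records(
            [(float(i), s, 1.0, None) for i, s in enumerate(sides)])
        assert neural.alternation_index(train) == pytest.approx(0.5, abs=0.02)


class TestFrequencyAndTotalSignal:
    def test_six_left_events_in_sixty_seconds(self):
        train = EventTrain.from_records(
            [(float(i * 10), "left", 1.0, None) for i in range(6)])
        assert neural.event_frequency(train, "left", 60.0) == pytest.approx(0.1)

    def test_no_events_zero_hz(self):
        assert neural.event_frequency(EventTrain.empty(), "left", 60.0) == 0.0

    def test_rate_recovery_from_long_simulation(self):
        params = syn.CPGSimParams(seed=10, event_rate=0.4, switch_prob=0.5,
                                  duration=600.0, noise_sd=0.5)
        traces, _ = syn.simulate_bilateral_traces(params)
        summary = neural.summarize_activity(traces)
        # per-side rate is half the fish-level rate under symmetric switching
        assert summary.left_frequency_hz == pytest.approx(0.2, abs=0.05)

    def test_total_signal_of_zero_and_constant(self):
        assert neural.total_signal(np.zeros(600), 10.0) == 0.0
        const = neural.total_signal(np.ones(601), 10.0)
        assert const == pytest.approx(60.0)

    def test_total_signal_matches_analytic_kernel_area(self):
        tau_r, tau_d, fps, amp = 0.2, 1.5, 100.0, 7.0
        kernel, _ = syn.calcium_kernel(tau_r, tau_d, fps, tail=1e-6)
        t_peak = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
        peak_val = np.exp(-t_peak / tau_d) - np.exp(-t_peak / tau_r)
        analytic = amp * (tau_d - tau_r) / peak_val
        assert neural.total_signal(amp * kernel, fps) == pytest.approx(analytic, rel=0.02)


class TestPipelineRecovery:
    def test_alternation_index_recovers_switch_probability(self, recovery_run):
        params, _, truth, summary = recovery_run
        assert summary.alternation_index == pytest.approx(params.switch_prob, abs=0.05)

    def test_detection_matches_ground_truth_train(self, recovery_run):
        _, _, truth, summary = recovery_run
        assert summary.n_events == pytest.approx(len(truth), rel=0.05)

    def test_by_pair_mode_agrees_with_merged_at_low_noise(self, recovery_run):
        params, traces, _, summary = recovery_run
        by_pair = neural.summarize_activity(traces, mode="by_pair")
        assert by_pair.alternation_index == pytest.approx(
            summary.alternation_index, abs=0.05)
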