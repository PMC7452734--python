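"""Normalization, pulse detection, burst grouping, classification, scoring."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hydracal import (
    FluorescenceTrace,
    Pulse,
    SimulationConfig,
    analyze_trace,
    classify_pulses,
    detect_pulses,
    group_bursts,
    normalize_trace,
    render_trace,
    score_detection,
    simulate_events,
    summarize_events,
)
from hydracal.events import robust_noise_sd

from conftest import make_snr_trace


def _dff(values, frame_rate=2.0):
    return FluorescenceTrace(np.asarray(values, dtype=float),
                             frame_rate=frame_rate, units="dff")


class TestNormalize:
    def test_constant_trace_maps_to_zero(self):
        trace = FluorescenceTrace(np.full(500, 42.0), frame_rate=2.0)
        dff = normalize_trace(trace)
        np.testing.assert_allclose(dff.values, 0.0, atol=1e-12)
        assert dff.units == "dff"

    def test_scale_invariance(self):
        config = SimulationConfig(seed=5, duration=600.0)
        trace = render_trace(simulate_events(config), config)
        a = normalize_trace(trace).values
        b = normalize_trace(dataclasses.replace(trace, values=3.7 * trace.values)).values
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)

    def test_bleaching_residual_is_small(self):
        # pure 30-min bleaching, no events: the normalized baseline should
        # be flat to well under 0.02 dF/F across the whole 2-h recording
        config = SimulationConfig(seed=0, cb_burst_rate=0, rp1_rate=0,
                                  noise_sd=0, bleach_tau=1800.0)
        trace = render_trace(simulate_events(config), config)
        dff = normalize_trace(trace, baseline_window=120.0).values
        assert dff.max() - dff.min() < 0.02

    def test_rejects_nonraw_units_and_bad_baseline(self):
        with pytest.raises(ValueError, match="raw-units"):
            normalize_trace(_dff(np.zeros(100)))
        trace = FluorescenceTrace(np.full(100, -5.0), frame_rate=2.0)
        with pytest.raises(ValueError, match="F0"):
            normalize_trace(trace)
        ok = FluorescenceTrace(np.full(100, 5.0), frame_rate=2.0)
        with pytest.raises(ValueError, match="baseline_window"):
            normalize_trace(ok, baseline_window=1.0)


class TestDetect:
    def test_flat_trace_yields_nothing(self):
        assert detect_pulses(_dff(np.zeros(1000))) == []

    def test_rejects_subframe_separation(self):
        with pytest.raises(ValueError, match="min_separation"):
            detect_pulses(_dff(np.zeros(100)), min_separation=0.1)

    def test_noiseless_pulses_found_at_true_times(self):
        from hydracal.synthetic import GroundTruthEvents

        config = SimulationConfig(seed=0, noise_sd=0.0, bleach_tau=np.inf,
                                  duration=700.0)
        truth = np.array([100.0, 200.0, 300.0, 400.0, 500.0])
        events = GroundTruthEvents(
            burst_windows=[(t - 1, t + 1) for t in truth],
            pulse_times=truth, pulse_classes=np.array(["CB"] * 5),
            duration=config.duration)
        trace = render_trace(events, config)
        pulses = detect_pulses(normalize_trace(trace))
        assert len(pulses) == 5
        detected = np.array([p.time for p in pulses])
        np.testing.assert_allclose(detected, truth, atol=0.5 + 1e-9)

    def test_matches_brute_force_scan_on_noiseless_trace(self):
        from hydracal.synthetic import GroundTruthEvents

        config = SimulationConfig(seed=0, noise_sd=0.0, bleach_tau=np.inf,
                                  duration=700.0)
        truth = np.array([100.0, 180.0, 260.0, 420.0])
        events = GroundTruthEvents(
            burst_windows=[(t - 1, t + 1) for t in truth],
            pulse_times=truth, pulse_classes=np.array(["CB"] * 4),
            duration=config.duration)
        dff = normalize_trace(render_trace(events, config))
        x = dff.values
        sigma = max(robust_noise_sd(x), 1e-12)
        brute = [i for i in range(1, len(x) - 1)
                 if x[i] > x[i - 1] and x[i] > x[i + 1]
                 and x[i] > 4.0 * sigma]
        detected = [round(p.time * dff.frame_rate) for p in detect_pulses(dff)]
        assert detected == brute

    def test_pulse_count_monotone_in_threshold(self):
        _, _, trace = make_snr_trace(3)
        dff = normalize_trace(trace)
        counts = [len(detect_pulses(dff, threshold_k=k))
                  for k in (2.0, 3.0, 4.0, 6.0, 8.0)]
        assert counts == sorted(counts, reverse=True)

    def test_snr5_detection_is_accurate(self):
        _, events, trace = make_snr_trace(0)
        pulses, _, _ = analyze_trace(trace)
        score = score_detection([p.time for p in pulses], events.pulse_times)
        assert score.f1 >= 0.95

    def test_pulse_invariants(self):
        _, _, trace = make_snr_trace(1)
        for p in detect_pulses(normalize_trace(trace)):
            assert p.amplitude > 0
            assert 0 <= p.prominence <= p.amplitude
            assert 0 <= p.time <= trace.duration

    def test_drift_invariance_of_pulse_number(self):
        # exponential drift at half the baseline, tau 15 min, must not
        # move the CB pulse count by more than 2%
        config, events, trace = make_snr_trace(7)
        _, _, base = analyze_trace(trace)
        drift = 0.5 * config.baseline * np.exp(-trace.times / 900.0)
        drifted = dataclasses.replace(trace, values=trace.values + drift)
        _, _, moved = analyze_trace(drifted)
        assert abs(moved.cb_pulse_number - base.cb_pulse_number) <= max(
            1, 0.02 * base.cb_pulse_number)


def _pulses_at(times, amp=1.0):
    return [Pulse(time=float(t), amplitude=amp, prominence=amp, width_s=1.0)
            for t in times]


class TestGroupBursts:
    def test_textbook_grouping(self):
        pulses = _pulses_at([10.0, 12.0, 14.0, 300.0])
        bursts = group_bursts(pulses, max_ipi=5.0, min_pulses=2)
        assert len(bursts) == 1
        assert bursts[0].onset == 10.0 and bursts[0].offset == 14.0
        assert len(bursts[0].pulses) == 3

    def test_all_gaps_too_large(self):
        assert group_bursts(_pulses_at([0.0, 50.0, 100.0]), max_ipi=10.0) == []

    def test_empty_input(self):
        assert group_bursts([]) == []

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            group_bursts(_pulses_at([5.0, 1.0]))

    def test_recovers_generator_burst_count_noiselessly(self):
        config = SimulationConfig(seed=6, noise_sd=0.0, bleach_tau=np.inf)
        events = simulate_events(config)
        trace = render_trace(events, config)
        _, bursts, _ = analyze_trace(trace)
        # a detector with min_pulses=2 can only see true bursts that
        # actually contain at least two pulses
        recoverable = sum(
            1 for w0, w1 in events.burst_windows
            if ((events.cb_times >= w0) & (events.cb_times <= w1)).sum() >= 2)
        assert len(bursts) == recoverable

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1000, allow_nan=False), min_size=0,
                    max_size=30),
           st.floats(1.0, 50.0), st.integers(1, 4))
    def test_grouping_properties(self, times, max_ipi, min_pulses):
        pulses = _pulses_at(sorted(times))
        bursts = group_bursts(pulses, max_ipi=max_ipi, min_pulses=min_pulses)
        for b in bursts:
            assert len(b.pulses) >= min_pulses
            assert b.onset == b.pulses[0].time
            assert b.offset == b.pulses[-1].time
            gaps = np.diff([p.time for p in b.pulses])
            assert np.all(gaps <= max_ipi + 1e-12)
        # bursts are maximal: consecutive bursts are separated by > max_ipi
        for prev, nxt in zip(bursts, bursts[1:]):
            assert nxt.pulses[0].time - prev.pulses[-1].time > max_ipi


class TestClassify:
    def test_all_burst_members_are_cb(self):
        pulses = _pulses_at([0.0, 2.0, 4.0])
        bursts = group_bursts(pulses, max_ipi=5.0)
        classify_pulses(pulses, bursts)
        assert all(p.pulse_class == "CB" for p in pulses)

    def test_muscle_tissue_forces_rp1_empty(self):
        # neural-style trace analyzed as ectoderm muscle: every pulse is
        # a CB candidate and the RP1 count must be zero
        _, _, trace = make_snr_trace(2)
        _, _, summary = analyze_trace(trace, tissue="ectoderm")
        assert summary.rp1_pulse_number == 0

    def test_isolated_small_pulses_are_rp1(self):
        pulses = _pulses_at([0.0, 2.0, 4.0]) + _pulses_at([100.0], amp=0.3)
        bursts = group_bursts(pulses, max_ipi=5.0)
        classify_pulses(pulses, bursts, amplitude_ratio=0.7)
        assert pulses[-1].pulse_class == "RP1"

    def test_isolated_large_pulse_flagged_unassigned(self):
        pulses = _pulses_at([0.0, 2.0, 4.0]) + _pulses_at([100.0], amp=1.5)
        bursts = group_bursts(pulses, max_ipi=5.0)
        classify_pulses(pulses, bursts, min_pulses=2)
        assert pulses[-1].pulse_class == "unassigned"
        classify_pulses(pulses, bursts, min_pulses=1)
        assert pulses[-1].pulse_class == "CB"

    def test_mixed_trace_class_accuracy(self):
        _, events, trace = make_snr_trace(0)
        pulses, _, _ = analyze_trace(trace)
        det = np.array([p.time for p in pulses])
        cls = np.array([p.pulse_class for p in pulses])
        correct = total = 0
        used = np.zeros(events.pulse_times.size, dtype=bool)
        for order in np.argsort(det):
            d = det[order]
            j = int(np.argmin(np.abs(events.pulse_times - d)))
            if abs(events.pulse_times[j] - d) <= 1.0 and not used[j]:
                used[j] = True
                total += 1
                correct += cls[order] == events.pulse_classes[j]
        assert total > 0 and correct / total >= 0.95

    def test_conservation_of_classes(self):
        _, _, trace = make_snr_trace(4)
        pulses, _, summary = analyze_trace(trace)
        unassigned = sum(1 for p in pulses if p.pulse_class == "unassigned")
        assert (summary.cb_pulse_number + summary.rp1_pulse_number
                + unassigned) == len(pulses)


class TestSummarize:
    def test_no_pulses_all_zero(self):
        s = summarize_events([], [], 7200.0)
        assert s.cb_pulse_number == s.rp1_pulse_number == s.burst_count == 0
        assert s.cb_total_time == s.cb_pulse_frequency == s.rp1_frequency == 0

    def test_single_burst_arithmetic(self):
        pulses = _pulses_at(np.linspace(0.0, 60.0, 6))
        bursts = group_bursts(pulses, max_ipi=15.0)
        classify_pulses(pulses, bursts)
        s = summarize_events(pulses, bursts, 7200.0)
        assert s.cb_pulse_number == 6
        assert s.cb_total_time == pytest.approx(60.0)
        assert s.cb_pulse_frequency == pytest.approx(6.0)
        assert s.burst_count == 1

    def test_rp1_frequency_per_hour(self):
        pulses = _pulses_at([100.0, 200.0, 300.0], amp=0.3)
        for p in pulses:
            p.pulse_class = "RP1"
        s = summarize_events(pulses, [], 3600.0)
        assert s.rp1_pulse_number == 3
        assert s.rp1_frequency == pytest.approx(3.0)
        assert s.rp1_total_time == pytest.approx(3.0)

    def test_bad_duration(self):
        with pytest.raises(ValueError):
            summarize_events([], [], 0.0)

    def test_mean_recovered_pulse_number_tracks_truth(self):
        # 100 short recordings: mean detected CB count within 5% of the
        # ground-truth mean CB count
        true_counts, det_counts = [], []
        for seed in range(100):
            config = SimulationConfig(seed=seed, duration=1800.0).with_snr(5.0)
            events = simulate_events(config)
            trace = render_trace(events, config)
            _, _, s = analyze_trace(trace)
            true_counts.append(events.cb_times.size)
            det_counts.append(s.cb_pulse_number)
        assert np.mean(det_counts) == pytest.approx(np.mean(true_counts),
                                                    rel=0.05)


class TestScoreDetection:
    def test_perfect_detection(self):
        s = score_detection([1.0, 2.0], [1.0, 2.0])
        assert s.precision == s.recall == s.f1 == 1.0

    def test_empty_detected_convention(self):
        s = score_detection([], [1.0, 2.0])
        assert s.precision == 1.0 and s.recall == 0.0 and s.f1 == 0.0

    def test_half_recall(self):
        s = score_detection([1.0], [1.0, 10.0])
        assert s.precision == 1.0
        assert s.recall == 0.5
        assert s.f1 == pytest.approx(2.0 / 3.0)

    def test_one_to_one_matching(self):
        # two detections near one truth: only one may match
        s = score_detection([1.0, 1.2], [1.0])
        assert s.n_matched == 1
        assert s.precision == 0.5

    def test_bad_tolerance(self):
        with pytest.raises(ValueError):
            score_detection([1.0], [1.0], tolerance=0.0)
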