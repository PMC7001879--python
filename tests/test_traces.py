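"""dF/F, event detection, triggered averages, peaks, bouts, registration."""

import math

import numpy as np
import pytest

from tuftpipe.errors import ConfigError, InsufficientDataError
from tuftpipe.synthdata import MovieStack, gcamp_kernel, events_to_trace
from tuftpipe.traces import (compute_dff, detect_events, detect_lick_bouts,
                             detect_whisk_bouts, extract_peaks, frame_average,
                             rigid_register, triggered_average, window_peak)


class TestComputeDff:
    def test_constant_trace_is_zero(self):
        dff = compute_dff(np.full(500, 7.0), 4.0)
        np.testing.assert_allclose(dff.values, 0.0)

    def test_step_doubling_gives_unity(self):
        # F0 -> 2 F0 step; just after the step the rolling baseline is still F0
        tr = np.concatenate([np.full(200, 50.0), np.full(200, 100.0)])
        dff = compute_dff(tr, 1.0, window_s=30)
        assert dff.values[205] == pytest.approx(1.0)
        assert dff.values[100] == pytest.approx(0.0)

    def test_gain_invariance(self, rng):
        tr = 100.0 + 10.0 * rng.random(600)
        a = compute_dff(tr, 4.0).values
        b = compute_dff(3.7 * tr, 4.0).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="offset"):
            compute_dff(np.zeros(500), 4.0)


class TestDetectEvents:
    def _trace(self, onsets, rng, rate=4.0, dur_s=500.0, amp=1.0, noise=0.1):
        k = gcamp_kernel(frame_rate_hz=rate)
        n = int(dur_s * rate)
        tr = amp * events_to_trace(onsets, [1.0] * len(onsets), k, n, rate)
        return tr + noise * rng.standard_normal(n)

    def test_flat_trace_has_no_events(self):
        from tuftpipe.traces import DffTrace
        assert detect_events(DffTrace(np.zeros(1000), 4.0)) == []

    def test_single_large_event_onset_within_one_frame(self, rng):
        from tuftpipe.traces import DffTrace
        tr = self._trace([100.0], rng, amp=1.0, noise=0.1)
        events = detect_events(DffTrace(tr, 4.0))
        assert len(events) == 1
        assert abs(events[0].onset_s - 100.0) <= 0.25 + 1e-9

    def test_event_train_recall_and_precision(self, rng):
        """0.2-Hz planted train over 500 s at default SNR: both >= 0.9."""
        from tuftpipe.traces import DffTrace
        onsets = np.arange(2.0, 498.0, 5.0)  # 0.2 Hz
        tr = self._trace(list(onsets), rng, amp=1.0, noise=0.1)
        events = detect_events(DffTrace(tr, 4.0))
        det = np.array([e.onset_s for e in events])
        matched = sum(np.min(np.abs(det - o)) <= 0.75 for o in onsets)
        recall = matched / len(onsets)
        precision = sum(np.min(np.abs(onsets - d)) <= 0.75 for d in det) / len(det)
        assert recall >= 0.9
        assert precision >= 0.9

    def test_invariant_to_gain_and_offset_before_dff(self, rng):
        tr = 100.0 + 30.0 * self._trace([50.0, 120.0], rng, dur_s=200.0)
        a = detect_events(compute_dff(tr, 4.0))
        b = detect_events(compute_dff(2.5 * tr, 4.0))
        assert [e.onset_frame for e in a] == [e.onset_frame for e in b]


class TestFrameAverage:
    def test_constant_and_single_pixel(self):
        data = np.full((5, 4, 4), 3.0, dtype=np.float32)
        data[2, 1, 1] += 16.0
        fa = frame_average(MovieStack(data=data, frame_rate_hz=4.0))
        assert fa[0] == pytest.approx(3.0)
        assert fa[2] == pytest.approx(3.0 + 16.0 / 16)

    def test_equals_mean_of_pixel_traces(self, rng):
        data = rng.random((10, 6, 6)).astype(np.float32)
        fa = frame_average(MovieStack(data=data, frame_rate_hz=4.0))
        np.testing.assert_allclose(fa, data.reshape(10, -1).mean(axis=1), rtol=1e-6)


class TestTriggeredAverage:
    def test_identical_segments_zero_sem(self):
        seg = np.sin(np.linspace(0, 3, 40))
        trace = np.tile(seg, 10)
        triggers = [10.0 * i + 1.0 for i in range(2, 8)]
        avg = triggered_average(trace, triggers, (1.0, 1.0), 4.0)
        assert avg.n_triggers == 6
        np.testing.assert_allclose(avg.sem, 0.0, atol=1e-12)

    def test_single_trigger_returns_segment(self):
        trace = np.arange(100.0)
        avg = triggered_average(trace, [10.0], (1.0, 2.0), 4.0)
        np.testing.assert_array_equal(avg.mean, trace[36:48])
        assert avg.n_triggers == 1

    def test_white_noise_average_within_clt_bound(self, rng):
        trace = rng.standard_normal(100_000)
        triggers = list(rng.uniform(10, 24_000, size=200))
        avg = triggered_average(trace, triggers, (1.0, 1.0), 4.0)
        assert np.all(np.abs(avg.mean) < 3.0 / math.sqrt(200) + 1e-12)

    def test_edge_triggers_dropped_and_counted(self):
        trace = np.zeros(100)
        avg = triggered_average(trace, [0.1, 12.0], (1.0, 1.0), 4.0)
        assert avg.n_triggers == 1
        assert avg.n_dropped == 1
        with pytest.raises(InsufficientDataError):
            triggered_average(trace, [0.1], (1.0, 1.0), 4.0)

    def test_linearity_of_pooled_triggers(self, rng):
        trace = rng.standard_normal(4000)
        t1 = list(rng.uniform(10, 900, 40))
        t2 = list(rng.uniform(10, 900, 60))
        a = triggered_average(trace, t1, (1.0, 1.0), 4.0)
        b = triggered_average(trace, t2, (1.0, 1.0), 4.0)
        ab = triggered_average(trace, t1 + t2, (1.0, 1.0), 4.0)
        pooled = (40 * a.mean + 60 * b.mean) / 100
        np.testing.assert_allclose(ab.mean, pooled, atol=1e-12)


def _avg_with_bump(peak_s, rate=30.0, pre=2.0, post=3.0, width=0.3, n=5):
    t = (np.arange(int((pre + post) * rate)) - int(pre * rate)) / rate
    from tuftpipe.traces import TriggeredAverage
    y = np.exp(-0.5 * ((t - peak_s) / width) ** 2)
    return TriggeredAverage(window_s=(pre, post), mean=y, sem=np.zeros_like(y),
                            n_triggers=n, frame_rate_hz=rate)


class TestExtractPeaks:
    def test_planted_second_peak_latency(self):
        avg = _avg_with_bump(1.5, rate=4.0)
        res = extract_peaks(avg, (-2.0, 0.2), (0.2, 2.5), interpolate=False)
        assert res.second_detected
        assert abs(res.second_latency_s - 1.5) <= 0.5 / 4.0 + 1e-9

    @pytest.mark.parametrize("rate", [4.0, 30.0])
    @pytest.mark.parametrize("delta", [0.25, 0.5])
    def test_shift_equivariance(self, rate, delta):
        base = window_peak(_avg_with_bump(1.0, rate=rate), (0.2, 2.0), True)[0]
        shifted = window_peak(_avg_with_bump(1.0 + delta, rate=rate),
                              (0.2, 2.8), True)[0]
        assert abs((shifted - base) - delta) <= 0.2 / rate + 1e-9

    def test_flat_and_monotone_traces_not_detected(self):
        from tuftpipe.traces import TriggeredAverage
        t = np.arange(20) / 4.0 - 2.0
        flat = TriggeredAverage((2.0, 3.0), np.zeros(20), np.zeros(20), 3, 4.0)
        mono = TriggeredAverage((2.0, 3.0), np.linspace(0, 1, 20), np.zeros(20), 3, 4.0)
        for avg in (flat, mono):
            res = extract_peaks(avg, (-1.0, 0.0), (0.2, 2.0))
            assert not res.first_detected and not res.second_detected

    def test_window_order_enforced(self):
        with pytest.raises(ConfigError):
            extract_peaks(_avg_with_bump(1.0), (0.0, 2.0), (1.0, 3.0))


class TestWhiskBouts:
    def test_constant_trace_no_bouts(self):
        assert len(detect_whisk_bouts(np.zeros(2000), 100.0)) == 0

    def test_lockout_suppresses_close_bouts(self, rng):
        theta = 0.3 * rng.standard_normal(2000)
        for onset in (5.0, 5.5):  # 0.5 s apart
            i = int(onset * 100)
            theta[i:i + 30] += 10.0
        onsets = detect_whisk_bouts(theta, 100.0)
        assert len(onsets) == 1

    def test_planted_bouts_recovered_within_window(self, rng):
        # slow setpoint wander (whisker angle is not white noise)
        from scipy.ndimage import gaussian_filter1d
        theta = gaussian_filter1d(20.0 * rng.standard_normal(30_000), 50)
        planted = np.arange(10) * 2.5 + 3.0
        amp = 5.0 * np.std(theta)
        for onset in planted:
            i = int(onset * 100)
            theta[i:i + 60] += amp
        onsets = detect_whisk_bouts(theta, 100.0)
        assert len(onsets) == 10
        for p in planted:
            assert np.min(np.abs(onsets - p)) <= 0.150
        # lockout invariant holds on every output
        assert np.all(np.diff(onsets) >= 1.0 - 1e-9)

    def test_short_trace_rejected(self):
        with pytest.raises(ConfigError):
            detect_whisk_bouts(np.zeros(5), 100.0)


class TestLickBouts:
    def test_gap_splits_bouts(self):
        bouts = detect_lick_bouts([1.0, 1.2, 5.0], max_gap_s=1.0)
        assert [b.onset_s for b in bouts] == [1.0, 5.0]

    def test_empty(self):
        assert detect_lick_bouts([]) == []

    def test_reward_proximity_flags_non_isolated(self):
        bouts = detect_lick_bouts([2.0], reward_times_s=[3.5], exclusion_s=3.0)
        assert not bouts[0].isolated
        far = detect_lick_bouts([2.0], reward_times_s=[30.0], exclusion_s=3.0)
        assert far[0].isolated


class TestRigidRegister:
    def test_still_movie_zero_shifts(self, rng):
        base = rng.random((8, 16, 16)).astype(np.float32)
        base[:] = base[0]
        _, shifts = rigid_register(MovieStack(base, 4.0))
        assert np.all(shifts == 0)

    def test_planted_integer_shifts_recovered(self, rng):
        frame = np.zeros((32, 32), dtype=np.float32)
        frame[10:20, 8:25] = rng.random((10, 17)) * 50 + 50
        planted = [(0, 0), (2, -1), (-2, 2), (1, 1), (0, -2)]
        data = np.stack([np.roll(frame, (-dy, -dx), axis=(0, 1))
                         for dy, dx in planted])
        reg, shifts = rigid_register(MovieStack(data, 4.0), max_shift_px=4)
        np.testing.assert_array_equal(shifts, np.array(planted))
        for f in reg.data:
            np.testing.assert_array_equal(f, frame)

    def test_pure_noise_bounded(self, rng):
        data = rng.random((6, 16, 16)).astype(np.float32)
        _, shifts = rigid_register(MovieStack(data, 4.0), max_shift_px=3)
        assert np.all(np.abs(shifts) <= 3)
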