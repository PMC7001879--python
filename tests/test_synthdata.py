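"""Behavioral-session generator, footprints, kernel, and movie rendering."""

import dataclasses
import math

import numpy as np
import pytest

from tuftpipe.errors import ConfigError
from tuftpipe.studies import random_reward_rate_study
from tuftpipe.synthdata import (DendriteClass, PopulationConfig, TaskConfig,
                                events_to_trace, footprint_extent,
                                gcamp_kernel, generate_session, kernel_peak_time,
                                make_footprint, place_events, render_movie)


class TestGenerateSession:
    def test_deterministic(self, small_task):
        a = generate_session(small_task, seed=7)
        b = generate_session(small_task, seed=7)
        assert [dataclasses.astuple(t) for t in a.trials] == \
               [dataclasses.astuple(t) for t in b.trials]
        assert a.random_reward_times_s == b.random_reward_times_s
        assert a.lick_times_s == b.lick_times_s
        np.testing.assert_array_equal(a.whisker_angle, b.whisker_angle)

    def test_zero_random_reward_probability(self):
        cfg = TaskConfig(n_trials=20, random_reward_prob=0.0)
        assert generate_session(cfg, seed=1).random_reward_times_s == []

    @pytest.mark.parametrize("bad", [
        dict(n_trials=0), dict(n_trials=2000), dict(frame_rate_hz=0.0),
        dict(go_fraction=1.5), dict(reward_delays_ms=(-10, 0)),
        dict(task_variant="bogus"),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigError):
            generate_session(TaskConfig(**bad), seed=0)

    def test_delay_proportions_near_uniform(self):
        # uniform per-Hit assignment; pooled over a few sessions the +/-0.06
        # band sits ~3 binomial SEs from 1/3
        cfg = TaskConfig(n_trials=300)
        delays = []
        for seed in (0, 1, 2):
            session = generate_session(cfg, seed=seed)
            delays += [t.reward_delay_ms for t in session.hit_trials()]
        assert len(delays) > 400
        for d in (0, 250, 500):
            frac = delays.count(d) / len(delays)
            assert abs(frac - 1 / 3) < 0.06

    def test_hit_reward_timing_invariant(self, small_session):
        for t in small_session.hit_trials():
            assert t.reward_time_s == pytest.approx(
                t.response_time_s + t.reward_delay_ms / 1000.0)
        for t in small_session.trials:
            if t.trial_type == "NoGo":
                assert t.first_contact_s is None

    def test_random_rewards_outside_trial_epochs(self, small_session):
        epochs = small_session.trial_epochs()
        for r in small_session.random_reward_times_s:
            assert not any(a <= r < b for a, b in epochs)

    def test_licking_follows_rewards(self):
        session = generate_session(TaskConfig(n_trials=80), seed=3)
        licks = np.asarray(session.lick_times_s)
        first_latencies, near_1s_rates = [], []
        for t in session.hit_trials():
            after = licks[licks >= t.response_time_s]
            first_latencies.append(after[0] - t.response_time_s)
            n = np.count_nonzero((licks >= t.response_time_s + 0.75)
                                 & (licks < t.response_time_s + 1.25))
            near_1s_rates.append(n / 0.5)
        assert 0.3 <= np.median(first_latencies) <= 0.45
        assert 4.0 <= np.mean(near_1s_rates) <= 7.0

    def test_whisker_trace_covers_session(self, small_session):
        n = len(small_session.whisker_angle)
        assert n / small_session.whisker_rate_hz >= small_session.duration_s - 0.05
        assert small_session.frame_times_s[0] == 0.0
        assert np.all(np.diff(small_session.frame_times_s) > 0)

    def test_random_reward_rate_calibration(self):
        # expected fraction of ITIs containing a random reward in [2%, 5%]
        r = random_reward_rate_study(seed=0, n_sessions=50, n_trials=30)
        lo = 0.02 - 3 * r["binomial_se"]
        hi = 0.05 + 3 * r["binomial_se"]
        assert lo <= r["fraction_with_reward"] <= hi


class TestMakeFootprint:
    def test_deterministic_and_normalized(self):
        a = make_footprint(128, 0.7, 50, 1, seed=5)
        b = make_footprint(128, 0.7, 50, 1, seed=5)
        np.testing.assert_array_equal(a, b)
        assert a.max() == pytest.approx(1.0)
        assert np.all(a >= 0)

    @pytest.mark.parametrize("length,branches", [(40, 0), (60, 2), (100, 1)])
    def test_extent_at_least_length(self, length, branches):
        img = make_footprint(128, 1.1, length, branches, seed=2)
        assert footprint_extent(img) >= length

    def test_too_long_for_frame(self):
        with pytest.raises(ConfigError):
            make_footprint(64, 0.0, 200, 0, seed=0)
        with pytest.raises(ConfigError):
            make_footprint(64, 0.0, 1, 0, seed=0)


class TestGcampKernel:
    def test_peak_time_matches_closed_form(self):
        # t* = ln(decay/rise) * rise * decay / (decay - rise)
        k = gcamp_kernel(0.05, 0.6, frame_rate_hz=100.0)
        t_star = kernel_peak_time(0.05, 0.6)
        assert abs(np.argmax(k) / 100.0 - t_star) <= 0.01
        assert k.max() == pytest.approx(1.0)

    def test_causal_and_nonnegative(self):
        k = gcamp_kernel(0.1, 0.8, frame_rate_hz=20.0)
        assert np.all(k >= 0)
        assert np.isfinite(k.sum())
        # support strictly at t >= 0: convolving a delta leaves the past at 0
        tr = events_to_trace([5.0], [1.0], k, 200, 20.0)
        assert np.all(tr[: int(5.0 * 20)] == 0)

    def test_low_rate_kernel_is_bin_average(self):
        # at 4 Hz the kernel is the continuous response integrated per 250-ms
        # bin, not a point sample; written out independently here
        k4 = gcamp_kernel(0.05, 0.6, frame_rate_hz=4.0)
        n_bins = math.ceil(8 * 0.6 / 0.25)
        tf = (np.arange(n_bins * 250) + 0.5) * 1e-3
        h = np.exp(-tf / 0.6) - np.exp(-tf / 0.05)
        binned = h.reshape(n_bins, 250).mean(axis=1)
        binned /= binned.max()
        assert len(k4) == n_bins
        np.testing.assert_allclose(k4, binned, atol=1e-9)

    def test_invalid_kinetics(self):
        with pytest.raises(ConfigError):
            gcamp_kernel(0.6, 0.5, 10.0)


class TestRenderMovie:
    def test_deterministic(self, small_session):
        pop = PopulationConfig(n_dendrites=3)
        a, _ = render_movie(small_session, pop, seed=9, frame_size_px=32)
        b, _ = render_movie(small_session, pop, seed=9, frame_size_px=32)
        np.testing.assert_array_equal(a.data, b.data)

    def test_noise_free_reconstruction_exact(self, small_session):
        pop = PopulationConfig(n_dendrites=4, read_noise_sd=0.0,
                               shot_noise_gain=0.0)
        stack, gt = render_movie(small_session, pop, seed=4, frame_size_px=48)
        A = np.stack([fp.ravel() for fp in gt.footprints], axis=1)
        recon = (A @ gt.traces).T.reshape(stack.n_frames, 48, 48)
        recon += gt.background_image[None] * gt.background_trace[:, None, None]
        assert np.max(np.abs(stack.data - recon.astype(np.float32))) == 0.0

    def test_zero_amplitude_population_is_flat(self, small_session):
        pop = PopulationConfig(n_dendrites=4, contact_amp=0.0, reward_amp=0.0,
                               iti_rate_hz=0.0, spont_rate_hz=0.0,
                               read_noise_sd=0.0, shot_noise_gain=0.0)
        stack, gt = render_movie(small_session, pop, seed=4, frame_size_px=32)
        assert all(len(o) == 0 for o in gt.transient_onsets_s)
        fa = stack.data.reshape(stack.n_frames, -1).mean(axis=1)
        # only the 3% background drift remains
        assert np.ptp(fa) / fa.mean() < 0.07

    def test_single_event_movie_is_rank_one(self, small_session):
        """One dendrite, one planted transient, no noise: every active frame
        is proportional to the footprint and follows the kernel."""
        pop = PopulationConfig(n_dendrites=1,
                               class_fractions={"contact_only": 1.0},
                               read_noise_sd=0.0, shot_noise_gain=0.0,
                               baseline_counts=0.0, spont_rate_hz=0.0)
        stack, gt = render_movie(small_session, pop, seed=6, frame_size_px=32)
        onsets = gt.transient_onsets_s[0]
        assert len(onsets) > 0
        fp = gt.footprints[0]
        p = np.unravel_index(np.argmax(fp), fp.shape)
        trace = stack.data[:, p[0], p[1]]
        active = trace > 1e-9
        assert active.any()
        # frames are scalar multiples of the footprint
        for i in np.where(active)[0][:10]:
            frame = stack.data[i]
            scale = frame[p] / fp[p]
            np.testing.assert_allclose(frame, scale * fp, atol=1e-4 * frame.max())
        # temporal profile equals the planted clean trace exactly
        np.testing.assert_allclose(trace, fp[p] * gt.traces[0], rtol=1e-6)

    def test_contact_events_placed_at_planted_latency(self, small_session):
        pop = PopulationConfig(contact_jitter_s=0.0,
                               contact_latency_dendrite_sd_s=0.0,
                               spont_rate_hz=0.0)
        rng = np.random.default_rng(0)
        dc = DendriteClass(label="contact_only")
        onsets, _ = place_events(small_session, dc, pop, rng)
        contacts = np.array([t.first_contact_s for t in small_session.trials
                             if t.first_contact_s is not None])
        for o in onsets:
            assert np.min(np.abs(contacts + 0.58 - o)) < 1e-9

    def test_reward_class_onsets_lock_to_rewards(self, small_session):
        pop = PopulationConfig(reward_jitter_s=0.0, reward_lag_dendrite_sd_s=0.0,
                               iti_rate_hz=0.0, spont_rate_hz=0.0)
        rng = np.random.default_rng(1)
        dc = DendriteClass(label="reward_tracking", contact_amp=0.0)
        onsets, _ = place_events(small_session, dc, pop, rng)
        rewards = np.array([t.reward_time_s for t in small_session.hit_trials()])
        assert len(onsets) > 0
        for o in onsets:
            assert np.min(np.abs(rewards + pop.reward_lag_s - o)) < 1e-9

    def test_full_trial_suppression_silences_trials(self, small_session):
        pop = PopulationConfig(spont_rate_hz=0.0, iti_rate_hz=0.1)
        rng = np.random.default_rng(2)
        dc = DendriteClass(label="random_reward_pretrial", reward_amp=0.0,
                           trial_suppression=1.0)
        onsets, _ = place_events(small_session, dc, pop, rng)
        epochs = small_session.trial_epochs()
        assert len(onsets) > 0
        assert not any(a <= o < b for o in onsets for a, b in epochs)

    def test_lever_only_variant_mutes_reward_responses(self):
        cfg = TaskConfig(n_trials=30, task_variant="lever_only")
        session = generate_session(cfg, seed=7)
        pop = PopulationConfig(iti_rate_hz=0.0, spont_rate_hz=0.0)
        rng = np.random.default_rng(3)
        dc = DendriteClass(label="random_reward_pretrial")
        onsets, _ = place_events(session, dc, pop, rng)
        assert onsets == []
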