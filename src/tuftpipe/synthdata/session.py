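"""Go/NoGo behavioral session generator.

Emulates a head-fixed whisker-based pole detection task: the mouse holds a
lever for >= 1 s to initiate a trial, a pole moves into (Go) or away from
(NoGo) the whisker field, and a lever lift within a 3-s window is a Hit
(rewarded, with a per-trial reward delay drawn from a small set) on Go trials
or a FalseAlarm (timeout) on NoGo trials.  Unearned "random" rewards are
dropped during a small fraction of inter-trial intervals, licking bouts
follow every reward, and a whisker-angle trace with planted whisking bouts is
synthesized alongside the event log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..errors import ConfigError

__all__ = ["TaskConfig", "TrialRecord", "BehavioralSession", "generate_session"]


@dataclass
class TaskConfig:
    """Parameters of one simulated behavioral session.

    Defaults reflect a trained animal on the pole-detection task: 150 trials,
    a 1-s lever hold, a 3-s response window, reward delays of 0/250/500 ms,
    random inter-trial rewards calibrated so that roughly 2-5% of ITIs contain
    one, a 9-s false-alarm timeout, and 4-fps imaging.
    """

    n_trials: int = 150
    go_fraction: float = 0.7
    lever_hold_s: float = 1.0
    response_window_s: float = 3.0
    reward_delays_ms: tuple = (0, 250, 500)
    random_reward_prob: float = 0.007  # per inter-trial second (~4.5% of ITIs)
    timeout_s: float = 9.0
    reward_volume_ul: float = 8.0  # metadata only
    frame_rate_hz: float = 4.0
    frame_size_px: int = 128
    session_duration_cap_s: Optional[float] = None
    # distribution of inter-trial interval durations (uniform bounds, s);
    # exposed because the task protocol does not pin it down
    iti_range_s: tuple = (6.0, 12.0)
    hit_rate: float = 0.9
    false_alarm_rate: float = 0.15
    drink_period_s: float = 3.0
    contact_latency_mean_s: float = 0.37  # first contact after pole onset
    contact_latency_sd_s: float = 0.10
    response_latency_mean_s: float = 1.3  # lever lift after pole onset
    response_latency_sd_s: float = 0.2
    lick_bout_duration_s: float = 2.5
    spont_lick_bout_prob: float = 0.25  # per ITI
    spont_whisk_bout_prob: float = 0.3  # per ITI
    whisker_rate_hz: float = 100.0
    task_variant: str = "pole_detection"  # or "lever_only"

    def validate(self) -> None:
        if not (1 <= self.n_trials <= 1000):
            raise ConfigError(f"n_trials must be in [1, 1000], got {self.n_trials}")
        if not (0.0 <= self.go_fraction <= 1.0):
            raise ConfigError(f"go_fraction must be in [0, 1], got {self.go_fraction}")
        if any(d < 0 for d in self.reward_delays_ms):
            raise ConfigError("reward delays must be non-negative")
        if self.frame_rate_hz <= 0:
            raise ConfigError(f"frame_rate_hz must be positive, got {self.frame_rate_hz}")
        if self.frame_size_px <= 0:
            raise ConfigError("frame_size_px must be positive")
        if not (0.0 <= self.random_reward_prob <= 1.0):
            raise ConfigError("random_reward_prob must be a probability")
        if self.iti_range_s[0] <= 0 or self.iti_range_s[1] < self.iti_range_s[0]:
            raise ConfigError(f"invalid iti_range_s {self.iti_range_s}")
        if self.task_variant not in ("pole_detection", "lever_only"):
            raise ConfigError(f"unknown task_variant {self.task_variant!r}")


@dataclass
class TrialRecord:
    """One trial of the detection task.

    For Hits ``reward_time_s = response_time_s + reward_delay_ms / 1000``.
    NoGo trials never have a first contact.
    """

    trial_index: int
    trial_type: str  # "Go" | "NoGo"
    press_time_s: float
    pole_onset_s: float
    outcome: str  # "Hit" | "Miss" | "FalseAlarm" | "CorrectReject"
    trial_end_s: float
    first_contact_s: Optional[float] = None
    response_time_s: Optional[float] = None
    reward_delay_ms: Optional[int] = None
    reward_time_s: Optional[float] = None

    def validate(self) -> None:
        if self.trial_type == "NoGo" and self.first_contact_s is not None:
            raise ConfigError("NoGo trials have no first contact")
        if self.outcome == "Hit":
            if self.reward_time_s is None or self.response_time_s is None:
                raise ConfigError("Hit trials carry a response and a reward")
            expected = self.response_time_s + self.reward_delay_ms / 1000.0
            if abs(self.reward_time_s - expected) > 1e-9:
                raise ConfigError("reward_time_s inconsistent with delay")


@dataclass
class BehavioralSession:
    """Timeline of trials, rewards, licks and whisker angle for one session."""

    trials: list  # list[TrialRecord]
    random_reward_times_s: list
    lick_times_s: list
    whisker_angle: np.ndarray
    whisker_rate_hz: float
    frame_times_s: np.ndarray
    session_id: str = "session-0"
    task_variant: str = "pole_detection"
    frame_rate_hz: float = 4.0

    @property
    def duration_s(self) -> float:
        return float(self.frame_times_s[-1] + 1.0 / self.frame_rate_hz)

    @property
    def n_frames(self) -> int:
        return len(self.frame_times_s)

    def trial_epochs(self) -> list:
        """(start, end) of every trial, press through trial end."""
        return [(t.press_time_s, t.trial_end_s) for t in self.trials]

    def iti_segments(self) -> list:
        """(start, end) of every inter-trial interval, including the leading one."""
        segs = []
        prev_end = 0.0
        for t in self.trials:
            if t.press_time_s > prev_end:
                segs.append((prev_end, t.press_time_s))
            prev_end = t.trial_end_s
        if self.duration_s > prev_end:
            segs.append((prev_end, self.duration_s))
        return segs

    def reward_times(self) -> list:
        """All reward deliveries (trial rewards then random rewards), sorted."""
        times = [t.reward_time_s for t in self.trials if t.reward_time_s is not None]
        return sorted(times + list(self.random_reward_times_s))

    def hit_trials(self) -> list:
        return [t for t in self.trials if t.outcome == "Hit"]


def _lick_bout(rng: np.random.Generator, start_s: float, duration_s: float) -> list:
    """Lick times for one consummatory bout.

    The instantaneous rate ramps from ~2 licks/s at bout onset to ~5.5 licks/s
    0.6 s later and stays there for the rest of the bout.
    """
    licks = []
    t = start_s
    while t < start_s + duration_s:
        licks.append(t)
        phase = t - start_s
        rate = 2.0 + 3.5 * min(phase / 0.6, 1.0)
        gap = (1.0 / rate) * (1.0 + 0.15 * float(rng.standard_normal()))
        t += max(gap, 0.05)
    return licks


def _spont_lick_bout(rng: np.random.Generator, start_s: float) -> list:
    n = int(rng.integers(3, 7))
    gaps = np.clip(rng.normal(0.2, 0.03, size=n - 1), 0.1, 0.4)
    return list(start_s + np.concatenate([[0.0], np.cumsum(gaps)]))


def generate_session(cfg: TaskConfig, seed: int) -> BehavioralSession:
    """Simulate one behavioral session; identical (cfg, seed) give identical output."""
    cfg.validate()
    rng = np.random.default_rng(seed)

    trials = []
    licks: list = []
    whisk_bouts: list = []  # (onset, duration, amplitude)
    t = 0.0
    for i in range(cfg.n_trials):
        iti = float(rng.uniform(*cfg.iti_range_s))
        press = t + iti
        pole_on = press + cfg.lever_hold_s
        is_go = bool(rng.random() < cfg.go_fraction)
        # mice typically whisk when the pole motor starts to move
        whisk_bouts.append((pole_on + float(rng.uniform(0.0, 0.2)),
                            float(rng.uniform(0.5, 1.5)), float(rng.uniform(8, 15))))
        first_contact = response = reward = None
        delay = None
        if is_go:
            first_contact = pole_on + max(0.05, float(
                rng.normal(cfg.contact_latency_mean_s, cfg.contact_latency_sd_s)))
            if rng.random() < cfg.hit_rate:
                lat = float(rng.normal(cfg.response_latency_mean_s,
                                       cfg.response_latency_sd_s))
                lat = min(max(lat, 0.6), cfg.response_window_s - 0.05)
                response = pole_on + lat
                delay = int(rng.choice(list(cfg.reward_delays_ms)))
                reward = response + delay / 1000.0
                outcome = "Hit"
                end = reward + cfg.drink_period_s
                licks.extend(_lick_bout(rng, response + float(rng.uniform(0.3, 0.4)),
                                        cfg.lick_bout_duration_s))
            else:
                outcome = "Miss"
                end = pole_on + cfg.response_window_s
        else:
            if rng.random() < cfg.false_alarm_rate:
                response = pole_on + float(rng.uniform(0.5, cfg.response_window_s))
                outcome = "FalseAlarm"
                end = response + cfg.timeout_s
            else:
                outcome = "CorrectReject"
                end = pole_on + cfg.response_window_s
        trials.append(TrialRecord(
            trial_index=i, trial_type="Go" if is_go else "NoGo",
            press_time_s=press, pole_onset_s=pole_on, outcome=outcome,
            trial_end_s=end, first_contact_s=first_contact,
            response_time_s=response, reward_delay_ms=delay, reward_time_s=reward))
        t = end
        if cfg.session_duration_cap_s is not None and t >= cfg.session_duration_cap_s:
            break

    session_end = t + float(rng.uniform(*cfg.iti_range_s))

    # random rewards: one Bernoulli draw per whole inter-trial second, kept
    # >= 1 s clear of the adjacent trial epochs
    random_rewards: list = []
    prev_end = 0.0
    iti_bounds = []
    for tr in trials:
        iti_bounds.append((prev_end, tr.press_time_s))
        prev_end = tr.trial_end_s
    iti_bounds.append((prev_end, session_end))
    for (a, b) in iti_bounds:
        lo, hi = a + 1.0, b - 1.0
        n_slots = max(0, int(math.floor(hi - lo)))
        for s in range(n_slots):
            if rng.random() < cfg.random_reward_prob:
                rr = lo + s + float(rng.uniform(0.0, 1.0))
                random_rewards.append(rr)
                licks.extend(_lick_bout(rng, rr + float(rng.uniform(0.3, 0.4)),
                                        cfg.lick_bout_duration_s))
    # spontaneous lick and whisk bouts in ITIs
    for (a, b) in iti_bounds:
        if b - a > 3.5 and rng.random() < cfg.spont_lick_bout_prob:
            licks.extend(_spont_lick_bout(rng, float(rng.uniform(a + 1.5, b - 2.0))))
        if b - a > 4.5 and rng.random() < cfg.spont_whisk_bout_prob:
            whisk_bouts.append((float(rng.uniform(a + 1.5, b - 3.0)),
                                float(rng.uniform(0.5, 2.0)), float(rng.uniform(8, 15))))

    frame_times = np.arange(0.0, session_end, 1.0 / cfg.frame_rate_hz)

    # cover slightly past the last imaging frame
    whisker = _whisker_trace(rng, session_end + 1.0, cfg.whisker_rate_hz,
                             whisk_bouts)

    return BehavioralSession(
        trials=trials,
        random_reward_times_s=sorted(random_rewards),
        lick_times_s=sorted(licks),
        whisker_angle=whisker,
        whisker_rate_hz=cfg.whisker_rate_hz,
        frame_times_s=frame_times,
        session_id=f"sim-{seed}",
        task_variant=cfg.task_variant,
        frame_rate_hz=cfg.frame_rate_hz,
    )


def _whisker_trace(rng: np.random.Generator, duration_s: float, rate_hz: float,
                   bouts: list) -> np.ndarray:
    """Ornstein-Uhlenbeck setpoint noise plus planted whisking bouts (deg)."""
    n = int(math.ceil(duration_s * rate_hz)) + 1
    dt = 1.0 / rate_hz
    tau, sigma = 1.0, 1.0
    noise = rng.standard_normal(n)
    theta = np.empty(n)
    theta[0] = 0.0
    a = 1.0 - dt / tau
    b = sigma * math.sqrt(dt)
    for i in range(1, n):
        theta[i] = a * theta[i - 1] + b * noise[i]
    tgrid = np.arange(n) * dt
    for (onset, dur, amp) in bouts:
        mask = (tgrid >= onset) & (tgrid < onset + dur)
        if mask.any():
            # 8-Hz protraction oscillation riding on an amplitude step
            theta[mask] += amp * (0.6 + 0.4 * np.sin(2 * np.pi * 8.0 * (tgrid[mask] - onset)))
    return theta
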