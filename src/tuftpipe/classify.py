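"""Dendrite classification and population statistics.

Statistical conventions: alpha = 0.05 with no multiple-testing correction;
proportions are compared with a pooled two-proportion z-test (normal
approximation to the binomial); the random-reward responsiveness test is
one-sided (responsiveness is directional); latency-vs-delay relations use
ordinary least squares with delay expressed in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, InsufficientDataError
from .synthdata.session import BehavioralSession
from .traces import (CalciumEvent, DffTrace, TriggeredAverage,
                     detect_lick_bouts, triggered_average, window_peak)

__all__ = [
    "RegressionResult", "ProportionTestResult", "DendriteRecord", "AnalysisConfig",
    "two_proportion_test", "classify_reward_tracking", "classify_random_reward",
    "classify_contact", "activity_preference", "session_latency_regression",
    "session_second_peak_latencies", "learning_curve", "sort_by_peak_time",
    "build_dendrite_record", "predicted_label",
]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    p_value: float
    n: int
    r_squared: float


@dataclass
class ProportionTestResult:
    k1: int
    n1: int
    k2: int
    n2: int
    p1: float
    p2: float
    z: float
    p_value: float
    sided: str
    degenerate: bool = False


@dataclass
class DendriteRecord:
    """Per-dendrite activity summary and classification outcome."""

    dendrite_id: int
    pretrial_rate: float = 0.0
    trial_rate: float = 0.0
    activity_preference: str = "trial"
    is_reward_tracking: bool = False
    reward_tracking_regression: Optional[RegressionResult] = None
    is_random_reward_responsive: bool = False
    random_reward_test: Optional[ProportionTestResult] = None
    is_contact_responsive: bool = False
    predicted_class: str = "nonselective_timelocked"
    n_events: int = 0


@dataclass
class AnalysisConfig:
    """Windows and thresholds of the classification stage."""

    alpha: float = 0.05
    first_peak_window_s: tuple = (0.0, 2.0)    # after trial start
    second_peak_window_s: tuple = (0.2, 2.0)   # after lever lift
    event_window_s: float = 2.0                # post-reward event window
    contact_window_s: float = 1.0
    pretrial_window_s: float = 3.0
    control_exclusion_s: float = 3.0
    min_trials_per_delay: int = 3
    interpolate: bool = True
    control_seed: int = 0
    k_mad: float = 3.0
    min_event_duration_s: float = 0.5


def two_proportion_test(k1: int, n1: int, k2: int, n2: int,
                        sided: str = "two") -> ProportionTestResult:
    """Pooled two-proportion z-test.

    ``z = (p1 - p2) / sqrt(phat (1 - phat) (1/n1 + 1/n2))`` with
    ``phat = (k1 + k2) / (n1 + n2)``.  One-sided tests p1 > p2.  When the
    pooled proportion is 0 or 1 the statistic is undefined; the result is
    flagged degenerate with p = 1 (no evidence).
    """
    if n1 < 1 or n2 < 1:
        raise ConfigError("both sample sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ConfigError("counts must satisfy 0 <= k <= n")
    if sided not in ("two", "one"):
        raise ConfigError("sided must be 'two' or 'one'")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ProportionTestResult(k1, n1, k2, n2, p1, p2, z=0.0, p_value=1.0,
                                    sided=sided, degenerate=True)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    if sided == "two":
        p = 2.0 * float(stats.norm.sf(abs(z)))
    else:
        p = float(stats.norm.sf(z))
    return ProportionTestResult(k1, n1, k2, n2, p1, p2, z=z, p_value=min(p, 1.0),
                                sided=sided)


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    res = stats.linregress(x, y)
    p = float(res.pvalue) if len(x) >= 3 else math.nan
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            p_value=p, n=len(x), r_squared=float(res.rvalue) ** 2)


def classify_reward_tracking(avgs_by_delay: Dict[int, TriggeredAverage],
                             cfg: AnalysisConfig = AnalysisConfig()):
    """Reward-tracking test for one dendrite (or one session's frame average).

    ``avgs_by_delay`` maps reward delay (ms) to a lever-lift-aligned
    triggered average.  The second-peak latency of each delay condition with
    at least ``min_trials_per_delay`` triggers and a detected peak is
    regressed on delay (in seconds); the dendrite is reward tracking when the
    slope is positive and significant at alpha.

    Returns ``(flag, RegressionResult | None, reason)``.
    """
    xs, ys = [], []
    for delay_ms, avg in sorted(avgs_by_delay.items()):
        if avg.n_triggers < cfg.min_trials_per_delay:
            continue
        lat, _, det = window_peak(avg, cfg.second_peak_window_s, cfg.interpolate)
        if det:
            xs.append(delay_ms / 1000.0)
            ys.append(lat)
    if len(set(xs)) < 2:
        return False, None, "fewer than 2 usable delay conditions"
    reg = _ols(np.asarray(xs), np.asarray(ys))
    flag = bool(not math.isnan(reg.p_value) and reg.p_value < cfg.alpha
                and reg.slope > 0)
    return flag, reg, ""


def _eligible_control_starts(session: BehavioralSession, window_s: float,
                             exclusion_s: float) -> list:
    """ITI segments trimmed so a control window fits >= exclusion_s from any
    reward, lick bout, or trial boundary."""
    bad = []
    for r in session.reward_times():
        bad.append((r - exclusion_s, r + exclusion_s))
    for b in detect_lick_bouts(session.lick_times_s,
                               reward_times_s=session.reward_times()):
        bad.append((b.onset_s - exclusion_s, b.end_s + exclusion_s))
    segs = []
    for (a, b) in session.iti_segments():
        segs.append((a + exclusion_s, b - exclusion_s - window_s))
    # subtract bad intervals
    for (ba, bb) in sorted(bad):
        nxt = []
        for (a, b) in segs:
            if bb <= a or ba >= b:
                nxt.append((a, b))
            else:
                if ba - window_s > a:
                    nxt.append((a, ba - window_s))
                if bb < b:
                    nxt.append((bb, b))
        segs = nxt
    return [(a, b) for (a, b) in segs if b > a]


def classify_random_reward(events: Sequence[CalciumEvent],
                           session: BehavioralSession,
                           cfg: AnalysisConfig = AnalysisConfig()):
    """Random-reward responsiveness via an event-proportion comparison.

    p1 = fraction of random rewards followed by >= 1 event onset within
    ``event_window_s``; p2 = same fraction over an equal number of matched
    control windows drawn (seeded) from ITI epochs away from rewards, lick
    bouts and trial boundaries.  One-sided pooled z-test at alpha.

    Returns ``(flag, ProportionTestResult)``.
    """
    rr = list(session.random_reward_times_s)
    if len(rr) < 3:
        raise InsufficientDataError(
            f"need >= 3 random rewards, session has {len(rr)}")
    onsets = np.asarray([e.onset_s for e in events])
    w = cfg.event_window_s

    def hit(t0):
        return bool(np.any((onsets > t0) & (onsets <= t0 + w)))

    k1 = sum(hit(r) for r in rr)
    segs = _eligible_control_starts(session, w, cfg.control_exclusion_s)
    lengths = np.array([b - a for (a, b) in segs])
    if len(segs) == 0 or lengths.sum() <= 0:
        raise InsufficientDataError(
            f"no eligible control windows for {len(rr)} random rewards "
            f"(exclusion {cfg.control_exclusion_s} s)")
    rng = np.random.default_rng(cfg.control_seed)
    probs = lengths / lengths.sum()
    starts = []
    for _ in range(len(rr)):
        i = int(rng.choice(len(segs), p=probs))
        starts.append(float(rng.uniform(segs[i][0], segs[i][1])))
    k2 = sum(hit(s) for s in starts)
    test = two_proportion_test(k1, len(rr), k2, len(starts), sided="one")
    flag = bool(test.p_value < cfg.alpha and test.p1 > test.p2)
    return flag, test


def classify_contact(events: Sequence[CalciumEvent], session: BehavioralSession,
                     cfg: AnalysisConfig = AnalysisConfig()):
    """Contact responsiveness: events after first whisker contact versus
    matched pre-press control windows, one-sided pooled z-test."""
    contacts = [t.first_contact_s for t in session.trials
                if t.first_contact_s is not None]
    if len(contacts) < 3:
        return False, None
    onsets = np.asarray([e.onset_s for e in events])
    w = cfg.contact_window_s

    def hit(t0):
        return bool(np.any((onsets > t0) & (onsets <= t0 + w)))

    k1 = sum(hit(c) for c in contacts)
    trials_with_contact = [t for t in session.trials if t.first_contact_s is not None]
    controls = [t.press_time_s - 1.0 - w for t in trials_with_contact]
    controls = [c for c in controls if c >= 0]
    if not controls:
        return False, None
    k2 = sum(hit(c) for c in controls)
    test = two_proportion_test(k1, len(contacts), k2, len(controls), sided="one")
    return bool(test.p_value < cfg.alpha and test.p1 > test.p2), test


def activity_preference(events: Sequence[CalciumEvent],
                        session: BehavioralSession,
                        pretrial_window_s: float = 3.0):
    """Label a dendrite pretrial- or trial-active from pooled event rates.

    Pretrial rate pools ``[press - window, press)`` across trials; trial rate
    pools ``[press, reward or trial end)``.  Ties go to "trial".
    Returns ``(label, pretrial_rate, trial_rate)``.
    """
    if not session.trials:
        raise ConfigError("session has no trials")
    onsets = np.asarray([e.onset_s for e in events])
    pre_n = pre_t = tri_n = tri_t = 0.0
    for tr in session.trials:
        a = max(0.0, tr.press_time_s - pretrial_window_s)
        pre_t += tr.press_time_s - a
        pre_n += np.count_nonzero((onsets >= a) & (onsets < tr.press_time_s))
        end = tr.reward_time_s if tr.reward_time_s is not None else tr.trial_end_s
        tri_t += end - tr.press_time_s
        tri_n += np.count_nonzero((onsets >= tr.press_time_s) & (onsets < end))
    pre_rate = pre_n / pre_t if pre_t > 0 else 0.0
    tri_rate = tri_n / tri_t if tri_t > 0 else 0.0
    label = "pretrial" if pre_rate > tri_rate else "trial"
    return label, pre_rate, tri_rate


def session_second_peak_latencies(trace: np.ndarray, session: BehavioralSession,
                                  cfg: AnalysisConfig = AnalysisConfig(),
                                  pre_s: float = 2.0, post_s: float = 3.0) -> dict:
    """Per-delay second-peak latency of a session's population trace.

    Splits Hit trials by reward delay, builds lever-lift-aligned triggered
    averages of the (frame-average) trace, and extracts each condition's
    second-peak latency.  Conditions with too few trials or no detected peak
    are omitted.
    """
    by_delay: dict = {}
    for tr in session.hit_trials():
        by_delay.setdefault(tr.reward_delay_ms, []).append(tr.response_time_s)
    out = {}
    for delay_ms, lifts in sorted(by_delay.items()):
        if len(lifts) < cfg.min_trials_per_delay:
            continue
        try:
            avg = triggered_average(trace, lifts, (pre_s, post_s),
                                    session.frame_rate_hz)
        except InsufficientDataError:
            continue
        lat, _, det = window_peak(avg, cfg.second_peak_window_s, cfg.interpolate)
        if det:
            out[delay_ms] = lat
    return out


def session_latency_regression(latencies_by_delay: Sequence[dict]) -> RegressionResult:
    """Pooled regression of session second-peak latency on reward delay.

    ``latencies_by_delay`` holds one dict per session mapping delay (ms) to
    latency (s); delays enter the regression in seconds.
    """
    xs, ys = [], []
    for d in latencies_by_delay:
        for delay_ms, lat in d.items():
            xs.append(delay_ms / 1000.0)
            ys.append(lat)
    if len(set(xs)) < 2:
        raise InsufficientDataError("fewer than 2 delay conditions with latencies")
    return _ols(np.asarray(xs), np.asarray(ys))


def learning_curve(amplitudes: Sequence[float],
                   session_indices: Sequence[int]) -> RegressionResult:
    """Linear regression of random-reward peak amplitude on session index."""
    if len(amplitudes) < 3:
        raise InsufficientDataError("need >= 3 sessions")
    return _ols(np.asarray(session_indices, dtype=float),
                np.asarray(amplitudes, dtype=float))


def sort_by_peak_time(avgs: Sequence[TriggeredAverage],
                      ids: Optional[Sequence[int]] = None) -> list:
    """Order dendrites by the argmax time of their trial-aligned averages.

    Ties break deterministically by dendrite id.
    """
    if len(avgs) == 0:
        raise ConfigError("need at least one dendrite")
    if ids is None:
        ids = list(range(len(avgs)))
    keyed = []
    for i, avg in zip(ids, avgs):
        keyed.append((float(avg.times[int(np.argmax(avg.mean))]), i))
    return [i for (_, i) in sorted(keyed)]


def predicted_label(rec: DendriteRecord) -> str:
    """Map test outcomes to a single predicted class label."""
    if rec.is_reward_tracking:
        return "reward_tracking"
    if rec.is_random_reward_responsive:
        return "random_reward_pretrial"
    if rec.is_contact_responsive:
        return "contact_only"
    return "nonselective_timelocked"


def build_dendrite_record(dendrite_id: int, dff: DffTrace,
                          session: BehavioralSession,
                          cfg: AnalysisConfig = AnalysisConfig()) -> DendriteRecord:
    """Run the full per-dendrite classification battery on a dF/F trace."""
    from .traces import detect_events

    events = detect_events(dff, k_mad=cfg.k_mad,
                           min_duration_s=cfg.min_event_duration_s)
    rec = DendriteRecord(dendrite_id=dendrite_id, n_events=len(events))
    label, pre, tri = activity_preference(events, session, cfg.pretrial_window_s)
    rec.activity_preference, rec.pretrial_rate, rec.trial_rate = label, pre, tri

    # reward tracking from per-delay lever-lift-aligned averages of the trace
    by_delay: dict = {}
    for tr in session.hit_trials():
        by_delay.setdefault(tr.reward_delay_ms, []).append(tr.response_time_s)
    avgs = {}
    for delay_ms, lifts in by_delay.items():
        try:
            avgs[delay_ms] = triggered_average(dff.values, lifts, (2.0, 3.0),
                                               dff.frame_rate_hz)
        except InsufficientDataError:
            continue
    flag, reg, _ = classify_reward_tracking(avgs, cfg)
    rec.is_reward_tracking, rec.reward_tracking_regression = flag, reg

    if len(session.random_reward_times_s) >= 3:
        try:
            rflag, rtest = classify_random_reward(events, session, cfg)
            rec.is_random_reward_responsive, rec.random_reward_test = rflag, rtest
        except InsufficientDataError:
            pass
    cflag, _ = classify_contact(events, session, cfg)
    rec.is_contact_responsive = cflag
    rec.predicted_class = predicted_label(rec)
    return rec
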