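"""Trace-level analysis: dF/F, calcium events, triggered averages, peaks, bouts.

Conventions: time is seconds from session start; frame ``i`` spans
``[i/rate, (i+1)/rate)`` and an event at time ``t`` maps to frame
``floor(t * rate)``; analysis windows are half-open ``[t0, t1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d, percentile_filter

from .errors import ConfigError, DegenerateInputError, InsufficientDataError
from .synthdata.render import MovieStack

__all__ = [
    "DffTrace", "CalciumEvent", "TriggeredAverage", "PeakResult", "LickBout",
    "compute_dff", "detect_events", "frame_average", "extract_roi_trace",
    "triggered_average", "window_peak", "extract_peaks",
    "detect_whisk_bouts", "detect_lick_bouts", "rigid_register",
]


@dataclass
class DffTrace:
    """Relative fluorescence change per frame (dimensionless)."""

    values: np.ndarray
    frame_rate_hz: float
    baseline_method: str = "rolling-percentile-10-30s"

    def __len__(self):
        return len(self.values)


@dataclass
class CalciumEvent:
    onset_frame: int
    onset_s: float
    peak_amplitude: float
    duration_s: float


@dataclass
class TriggeredAverage:
    """Mean +/- SEM of trace segments aligned on trigger times."""

    window_s: tuple          # (pre, post), both positive
    mean: np.ndarray
    sem: np.ndarray
    n_triggers: int
    frame_rate_hz: float
    n_dropped: int = 0

    @property
    def times(self) -> np.ndarray:
        pre = int(round(self.window_s[0] * self.frame_rate_hz))
        return (np.arange(len(self.mean)) - pre) / self.frame_rate_hz


@dataclass
class PeakResult:
    """First (stimulus-locked) and second (reward-locked) peak of an average."""

    first_latency_s: float = math.nan
    first_amplitude: float = math.nan
    first_detected: bool = False
    second_latency_s: float = math.nan
    second_amplitude: float = math.nan
    second_detected: bool = False


@dataclass
class LickBout:
    onset_s: float
    end_s: float
    n_licks: int
    isolated: bool = True


def compute_dff(trace: np.ndarray, frame_rate_hz: float,
                window_s: float = 30.0, percentile: float = 10.0) -> DffTrace:
    """(F - F0) / F0 with F0 a rolling low-percentile baseline.

    The default baseline (10th percentile over a 30-s window) is robust to the
    dense transients of an engaged session.  Invariant under multiplicative
    gain applied to the raw trace.
    """
    trace = np.asarray(trace, dtype=float)
    size = max(1, int(round(window_s * frame_rate_hz)))
    if len(trace) < size:
        raise ConfigError(
            f"trace of {len(trace)} frames shorter than the {size}-frame baseline window")
    f0 = percentile_filter(trace, percentile, size=size, mode="nearest")
    if np.any(f0 <= 0):
        raise ValueError(
            "baseline F0 reaches zero; apply an offset correction before dF/F")
    return DffTrace(values=(trace - f0) / f0, frame_rate_hz=frame_rate_hz,
                    baseline_method=f"rolling-percentile-{percentile:g}-{window_s:g}s")


def detect_events(dff: DffTrace, k_mad: float = 3.0,
                  min_duration_s: float = 0.5,
                  merge_gap_s: float = 0.5) -> list:
    """Threshold-crossing calcium events.

    Onsets where dF/F crosses ``median + k_mad * MAD`` and stays above for at
    least ``min_duration_s``; one event per contiguous suprathreshold run.
    MAD is the normal-consistent (1.4826-scaled) median absolute deviation,
    so ``k_mad = 3`` means three robust standard deviations — the scaling is
    what keeps the false-event rate low enough for ~0.9 precision at
    realistic transient rates.  Runs separated by less than ``merge_gap_s``
    are merged first, so noise dips in a transient's decay tail do not
    re-trigger the detector.  The 0.5-s default minimum duration is two
    frames at 4 fps; a single-frame minimum would admit isolated noise
    frames as events.
    """
    x = dff.values
    if not np.all(np.isfinite(x)):
        raise ValueError("dF/F trace contains non-finite values")
    med = float(np.median(x))
    mad = 1.4826 * float(np.median(np.abs(x - med)))
    thr = med + k_mad * mad
    above = x > thr
    if not above.any():
        return []
    min_frames = max(1, int(math.ceil(min_duration_s * dff.frame_rate_hz)))
    # run-length encode the suprathreshold mask
    d = np.diff(above.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(x))
    gap_frames = int(round(merge_gap_s * dff.frame_rate_hz))
    merged = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < gap_frames:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events = []
    for s, e in merged:
        if e - s < min_frames:
            continue
        events.append(CalciumEvent(
            onset_frame=int(s),
            onset_s=s / dff.frame_rate_hz,
            peak_amplitude=float(x[s:e].max()),
            duration_s=(e - s) / dff.frame_rate_hz,
        ))
    return events


def frame_average(stack: MovieStack) -> np.ndarray:
    """Spatial mean fluorescence per frame (population activity trace)."""
    if stack.n_frames == 0:
        raise ConfigError("empty movie")
    return stack.data.reshape(stack.n_frames, -1).mean(axis=1)


def extract_roi_trace(stack: MovieStack, footprint: np.ndarray) -> np.ndarray:
    """Weighted-mean fluorescence of a footprint ROI (raw counts)."""
    w = footprint.ravel()
    total = w.sum()
    if total <= 0:
        raise DegenerateInputError("footprint has no positive weight")
    return stack.data.reshape(stack.n_frames, -1) @ (w / total)


def triggered_average(trace: np.ndarray, trigger_times_s: Sequence[float],
                      window_s: tuple, frame_rate_hz: float) -> TriggeredAverage:
    """Average trace segments aligned on triggers.

    ``window_s = (pre, post)`` in seconds on either side of the trigger.
    Triggers whose window leaves the trace are dropped and counted.
    """
    trace = np.asarray(trace, dtype=float)
    pre = int(round(window_s[0] * frame_rate_hz))
    post = int(round(window_s[1] * frame_rate_hz))
    segs = []
    dropped = 0
    for t in trigger_times_s:
        c = int(math.floor(t * frame_rate_hz))
        if c - pre < 0 or c + post > len(trace):
            dropped += 1
            continue
        segs.append(trace[c - pre:c + post])
    if not segs:
        raise InsufficientDataError(
            f"no usable triggers ({dropped} dropped at the trace edges)")
    seg = np.stack(segs)
    mean = seg.mean(axis=0)
    if len(segs) > 1:
        sem = seg.std(axis=0, ddof=1) / math.sqrt(len(segs))
    else:
        sem = np.zeros_like(mean)
    return TriggeredAverage(window_s=window_s, mean=mean, sem=sem,
                            n_triggers=len(segs), frame_rate_hz=frame_rate_hz,
                            n_dropped=dropped)


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample offset of a local maximum via a 3-point parabola."""
    if i <= 0 or i >= len(y) - 1:
        return 0.0
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom >= 0:
        return 0.0
    return float(0.5 * (y[i - 1] - y[i + 1]) / denom)


def window_peak(avg: TriggeredAverage, window_s: tuple,
                interpolate: bool = True):
    """Largest local maximum of the average within ``[w0, w1)``.

    Returns ``(latency_s, amplitude, detected)``.  Detection requires an
    interior maximum (a trace monotone through the window fails) and a
    prominence of at least 2 SD of the pre-trigger portion above its mean;
    with no pre-trigger samples the window minimum serves as the reference.
    """
    times = avg.times
    mask = (times >= window_s[0]) & (times < window_s[1])
    idx = np.where(mask)[0]
    if len(idx) == 0:
        return math.nan, math.nan, False
    y = avg.mean
    local = int(idx[np.argmax(y[idx])])
    amp = float(y[local])
    # reject window-edge maxima unless they are true local maxima of the
    # full trace: a monotone trace has no peak here
    if idx[0] < local < idx[-1]:
        interior = True
    else:
        interior = (0 < local < len(y) - 1
                    and y[local] > y[local - 1] and y[local] > y[local + 1])
    pre_mask = times < 0
    if pre_mask.any():
        base = float(y[pre_mask].mean())
        sd = float(y[pre_mask].std())
    else:
        base = float(y[idx].min())
        sd = 0.0
    detected = bool(interior and amp >= base + 2.0 * sd)
    lat = times[local]
    if interpolate:
        lat = lat + _parabolic_refine(y, local) / avg.frame_rate_hz
    return float(lat), amp, detected


def extract_peaks(avg: TriggeredAverage, first_window_s: tuple,
                  second_window_s: tuple, interpolate: bool = True) -> PeakResult:
    """First- and second-peak latencies/amplitudes of a triggered average."""
    if second_window_s[0] < first_window_s[1]:
        raise ConfigError("second window must start after the first window ends")
    f_lat, f_amp, f_det = window_peak(avg, first_window_s, interpolate)
    s_lat, s_amp, s_det = window_peak(avg, second_window_s, interpolate)
    return PeakResult(first_latency_s=f_lat, first_amplitude=f_amp,
                      first_detected=f_det, second_latency_s=s_lat,
                      second_amplitude=s_amp, second_detected=s_det)


def detect_whisk_bouts(theta: np.ndarray, sample_rate_hz: float,
                       window_s: float = 0.150, k_sd: float = 2.0,
                       lockout_s: float = 1.0,
                       stat_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Whisking-bout onsets from a sampled whisker-angle trace.

    The per-window angle change is max - min of theta within each sliding
    ``window_s`` window; onsets are threshold crossings at
    ``mean + k_sd * SD`` of the change distribution (optionally computed over
    a mask of baseline samples, e.g. inter-trial intervals), with subsequent
    onsets inside ``lockout_s`` suppressed.  Returned onsets are therefore
    always >= ``lockout_s`` apart.
    """
    theta = np.asarray(theta, dtype=float)
    w = int(round(window_s * sample_rate_hz))
    if len(theta) < w or w < 2:
        raise ConfigError("whisker trace shorter than the analysis window")
    hi = maximum_filter1d(theta, size=w, origin=-(w // 2))
    lo = minimum_filter1d(theta, size=w, origin=-(w // 2))
    change = (hi - lo)[: len(theta) - w + 1]
    if stat_mask is not None:
        ref = change[np.asarray(stat_mask[: len(change)], dtype=bool)]
        if len(ref) == 0:
            ref = change
    else:
        ref = change
    thr = float(ref.mean()) + k_sd * float(ref.std())
    above = change > thr
    if not above.any():
        return np.array([])
    crossings = np.where(above & ~np.concatenate([[False], above[:-1]]))[0]
    onsets = []
    last = -math.inf
    for i in crossings:
        t = i / sample_rate_hz
        if t - last >= lockout_s:
            onsets.append(t)
            last = t
    return np.array(onsets)


def detect_lick_bouts(lick_times_s: Sequence[float], max_gap_s: float = 1.0,
                      reward_times_s: Sequence[float] = (),
                      exclusion_s: float = 3.0) -> list:
    """Group licks into bouts; flag bouts near any reward as non-isolated.

    A gap > ``max_gap_s`` starts a new bout; a bout is non-isolated when its
    [first lick, last lick] span intersects any reward +/- ``exclusion_s``.
    """
    licks = np.asarray(sorted(lick_times_s), dtype=float)
    if len(licks) == 0:
        return []
    splits = np.where(np.diff(licks) > max_gap_s)[0] + 1
    bouts = []
    rewards = np.asarray(reward_times_s, dtype=float)
    for grp in np.split(licks, splits):
        onset, end = float(grp[0]), float(grp[-1])
        iso = not np.any((rewards >= onset - exclusion_s) & (rewards <= end + exclusion_s))
        bouts.append(LickBout(onset_s=onset, end_s=end, n_licks=len(grp), isolated=iso))
    return bouts


def rigid_register(stack: MovieStack, max_shift_px: int = 4):
    """Integer rigid registration against a running mean template.

    Per-frame (dy, dx) shifts maximize the cross-correlation with the running
    template of already-registered frames; shifts are clipped to
    ``+/- max_shift_px`` and applied circularly.  Returns ``(stack, shifts)``.
    """
    from skimage.registration import phase_cross_correlation

    if stack.n_frames == 0:
        raise ConfigError("empty movie")
    data = stack.data
    out = np.empty_like(data)
    shifts = np.zeros((stack.n_frames, 2), dtype=int)
    template = data[0].astype(float)
    out[0] = data[0]
    for i in range(1, stack.n_frames):
        shift, _, _ = phase_cross_correlation(template, data[i].astype(float),
                                              upsample_factor=1)
        dy, dx = (int(np.clip(s, -max_shift_px, max_shift_px)) for s in shift)
        shifts[i] = (dy, dx)
        out[i] = np.roll(data[i], (dy, dx), axis=(0, 1))
        template = template + (out[i].astype(float) - template) / (i + 1)
    return MovieStack(data=out, frame_rate_hz=stack.frame_rate_hz,
                      um_per_px=stack.um_per_px), shifts
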