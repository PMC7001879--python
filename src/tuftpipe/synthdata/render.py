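"""Forward model: dendrite classes -> event trains -> traces -> movie.

Five dendrite classes are planted:

``contact_only``
    fires ~580 ms after the first whisker-pole contact on Go trials.
``reward_tracking``
    contact responses plus a reward-locked transient at
    ``reward_time + lag``; because the reward is delivered at
    ``lever lift + delay``, its second calcium peak tracks the imposed delay
    with unit slope.
``random_reward_pretrial``
    responds to unearned rewards dropped in inter-trial intervals, carries a
    baseline ITI event rate, and is suppressed during trials
    (``trial_suppression`` = fraction of the ITI rate removed; 1 = silent in
    trials).
``nonselective_timelocked``
    fires at a fixed preferred phase relative to pole onset, so a population
    of them tiles the pre-trial and trial epochs.
``silent``
    nothing.

The movie is the superposition ``sum_i footprint_i x trace_i`` plus a smooth
background (spatial pattern x slow temporal drift) and Poisson-Gaussian noise
(shot noise approximated as intensity-scaled Gaussian).  In the
``lever_only`` task variant the identical population is rendered with all
reward-driven amplitudes set to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from ..errors import ConfigError
from .footprints import make_footprint
from .kinetics import gcamp_kernel
from .session import BehavioralSession

__all__ = [
    "DendriteClass", "PopulationConfig", "MovieStack", "GroundTruth",
    "place_events", "events_to_trace", "render_dendrite_trace",
    "build_population", "render_movie",
]

CLASS_LABELS = ("contact_only", "reward_tracking", "random_reward_pretrial",
                "nonselective_timelocked", "silent")


@dataclass
class DendriteClass:
    """Ground-truth generative label and amplitudes for one dendrite."""

    label: str
    contact_amp: float = 1.0  # dF/F units; generic amplitude for nonselective
    reward_amp: float = 1.0
    preferred_phase_s: float = 0.0  # vs pole onset (nonselective class)
    trial_suppression: float = 0.8  # fraction of ITI rate removed in trials
    # dendrite-to-dendrite heterogeneity (drawn once per dendrite)
    contact_latency_offset_s: float = 0.0
    reward_lag_offset_s: float = 0.0
    reliability_scale: float = 1.0

    def __post_init__(self):
        if self.label not in CLASS_LABELS:
            raise ConfigError(f"unknown dendrite class {self.label!r}")
        if self.contact_amp < 0 or self.reward_amp < 0:
            raise ConfigError("amplitudes must be non-negative")
        if not (0.0 <= self.trial_suppression <= 1.0):
            raise ConfigError("trial_suppression must be in [0, 1]")


@dataclass
class PopulationConfig:
    """Population composition and imaging/noise model for one movie."""

    n_dendrites: int = 20
    # fractions sum to <= 1; remainder is silent
    class_fractions: dict = field(default_factory=lambda: {
        "contact_only": 0.50,
        "reward_tracking": 0.12,
        "random_reward_pretrial": 0.09,
        "nonselective_timelocked": 0.29,
    })
    contact_amp: float = 1.0
    reward_amp: float = 1.0
    contact_latency_s: float = 0.58   # transient onset after first contact
    contact_jitter_s: float = 0.10
    reward_lag_s: float = 0.15        # transient onset after reward delivery
    reward_jitter_s: float = 0.05
    contact_reliability: float = 0.75
    reward_reliability: float = 0.9
    # across-dendrite spread of mean response latency and reliability; real
    # dendrites differ in contact tuning, which also decorrelates co-active
    # sources the way trial-by-trial participation does
    contact_latency_dendrite_sd_s: float = 0.10
    reward_lag_dendrite_sd_s: float = 0.05
    reliability_scale_range: tuple = (0.7, 1.2)
    iti_rate_hz: float = 0.02         # pretrial-class background event rate
    trial_suppression: float = 0.8
    nonselective_phase_range_s: tuple = (-3.0, 4.0)
    nonselective_reliability: float = 0.8
    phase_jitter_s: float = 0.15
    spont_rate_hz: float = 0.005      # all active classes
    amp_jitter_frac: float = 0.2      # multiplicative per-event amplitude jitter
    # kernel
    rise_s: float = 0.05
    decay_s: float = 0.6
    # imaging model (photon counts)
    baseline_counts: float = 100.0
    # counts per unit amplitude at weight 1; with the default baseline this
    # puts a unit-amplitude transient at ~100% dF/F, typical of tuft-wide
    # dendritic calcium spikes
    signal_counts: float = 100.0
    read_noise_sd: float = 2.0
    shot_noise_gain: float = 1.0      # 0 disables shot noise
    footprint_length_px: tuple = (40.0, 70.0)
    max_branches: int = 2
    um_per_px: float = 1.0

    def class_counts(self) -> dict:
        counts = {}
        assigned = 0
        for label, frac in self.class_fractions.items():
            k = int(round(frac * self.n_dendrites))
            counts[label] = k
            assigned += k
        counts["silent"] = max(0, self.n_dendrites - assigned)
        # rounding may overshoot; trim from the largest class
        while sum(counts.values()) > self.n_dendrites:
            big = max((l for l in counts if counts[l] > 0), key=lambda l: counts[l])
            counts[big] -= 1
        return counts


@dataclass
class MovieStack:
    """T x H x W nonnegative fluorescence stack with acquisition metadata."""

    data: np.ndarray
    frame_rate_hz: float
    um_per_px: float = 1.0

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ConfigError("movie data must be T x H x W")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.data.shape[1:]


@dataclass
class GroundTruth:
    """Everything planted into a synthetic movie."""

    footprints: list            # H x W weight images, one per dendrite
    classes: list               # DendriteClass per dendrite
    transient_onsets_s: list    # per-dendrite onset times
    transient_amps: list        # per-dendrite amplitudes (dF/F units)
    kernel: np.ndarray
    traces: Optional[np.ndarray] = None   # K x T clean traces (signal counts)
    background_image: Optional[np.ndarray] = None
    background_trace: Optional[np.ndarray] = None


def _in_trial(t: float, epochs: list) -> bool:
    return any(a <= t < b for (a, b) in epochs)


def place_events(session: BehavioralSession, dclass: DendriteClass,
                 pop: PopulationConfig, rng: np.random.Generator):
    """Draw ground-truth transient onsets and amplitudes for one dendrite."""
    lever_only = session.task_variant == "lever_only"
    onsets, amps = [], []
    epochs = session.trial_epochs()
    end = session.duration_s

    def add(t, a):
        if 0.0 <= t < end - 1.0 and a > 0:
            onsets.append(float(t))
            amps.append(float(a * (1.0 + pop.amp_jitter_frac * rng.standard_normal())))

    label = dclass.label
    # heterogeneity scales contact tuning only; reward responses of
    # reward-selective dendrites are reliable across the population
    c_rel = min(pop.contact_reliability * dclass.reliability_scale, 0.95)
    r_rel = pop.reward_reliability
    c_lat = pop.contact_latency_s + dclass.contact_latency_offset_s
    r_lag = pop.reward_lag_s + dclass.reward_lag_offset_s
    if label in ("contact_only", "reward_tracking"):
        for tr in session.trials:
            if tr.first_contact_s is None:
                continue
            if rng.random() < c_rel:
                add(tr.first_contact_s + c_lat
                    + pop.contact_jitter_s * rng.standard_normal(), dclass.contact_amp)
    if label == "reward_tracking" and not lever_only:
        for tr in session.hit_trials():
            if rng.random() < r_rel:
                add(tr.reward_time_s + r_lag
                    + pop.reward_jitter_s * rng.standard_normal(), dclass.reward_amp)
    if label == "random_reward_pretrial":
        if not lever_only:
            for rr in session.random_reward_times_s:
                if rng.random() < r_rel:
                    add(rr + r_lag
                        + pop.reward_jitter_s * rng.standard_normal(), dclass.reward_amp)
        # baseline ITI activity, thinned inside trials by trial_suppression
        n_bg = rng.poisson(pop.iti_rate_hz * end)
        bg_amp = 0.8 * max(dclass.reward_amp, dclass.contact_amp)
        for t in np.sort(rng.uniform(0.0, end, size=n_bg)):
            keep = 1.0 - dclass.trial_suppression if _in_trial(t, epochs) else 1.0
            if rng.random() < keep:
                add(t, bg_amp)
    if label == "nonselective_timelocked":
        for tr in session.trials:
            if rng.random() < pop.nonselective_reliability:
                add(tr.pole_onset_s + dclass.preferred_phase_s
                    + pop.phase_jitter_s * rng.standard_normal(), dclass.contact_amp)
    if label != "silent" and pop.spont_rate_hz > 0:
        n_sp = rng.poisson(pop.spont_rate_hz * end)
        for t in rng.uniform(0.0, end, size=n_sp):
            add(t, max(dclass.contact_amp, dclass.reward_amp) * 0.8)

    order = np.argsort(onsets) if onsets else []
    return [onsets[i] for i in order], [amps[i] for i in order]


def events_to_trace(onsets, amps, kernel: np.ndarray, n_frames: int,
                    frame_rate_hz: float) -> np.ndarray:
    """Convolve an event train with the calcium kernel on the frame grid.

    Events are placed with sub-frame precision by splitting each impulse
    linearly between the two neighboring frames.
    """
    delta = np.zeros(n_frames)
    for t, a in zip(onsets, amps):
        x = t * frame_rate_hz
        i = int(np.floor(x))
        w = x - i
        if 0 <= i < n_frames:
            delta[i] += a * (1.0 - w)
        if 0 <= i + 1 < n_frames:
            delta[i + 1] += a * w
    return np.convolve(delta, kernel)[:n_frames]


def render_dendrite_trace(session: BehavioralSession, dclass: DendriteClass,
                          pop: PopulationConfig, rng: np.random.Generator,
                          noise: bool = True):
    """Raw fluorescence trace for a single dendrite ROI (counts).

    Trace-level stand-in for imaging + segmentation + ROI extraction: the
    planted event train convolved with the kernel, scaled to signal counts on
    a constant baseline, with Poisson-Gaussian noise.  Returns
    ``(trace, onsets, amps)``.
    """
    kernel = gcamp_kernel(pop.rise_s, pop.decay_s, session.frame_rate_hz)
    onsets, amps = place_events(session, dclass, pop, rng)
    clean = pop.baseline_counts + pop.signal_counts * events_to_trace(
        onsets, amps, kernel, session.n_frames, session.frame_rate_hz)
    if noise:
        sd = np.sqrt(pop.read_noise_sd ** 2 + pop.shot_noise_gain * clean)
        clean = clean + sd * rng.standard_normal(len(clean))
    return clean, onsets, amps


def build_population(pop: PopulationConfig, rng: np.random.Generator) -> list:
    """Instantiate the per-dendrite class labels and parameters."""
    classes = []
    for label, count in pop.class_counts().items():
        for _ in range(count):
            classes.append(DendriteClass(
                label=label,
                contact_amp=pop.contact_amp,
                reward_amp=pop.reward_amp,
                preferred_phase_s=float(rng.uniform(*pop.nonselective_phase_range_s)),
                trial_suppression=pop.trial_suppression,
                contact_latency_offset_s=float(
                    rng.normal(0.0, pop.contact_latency_dendrite_sd_s)),
                reward_lag_offset_s=float(
                    rng.normal(0.0, pop.reward_lag_dendrite_sd_s)),
                reliability_scale=float(rng.uniform(*pop.reliability_scale_range)),
            ))
    rng.shuffle(classes)
    return classes


def render_movie(session: BehavioralSession, pop: PopulationConfig, seed: int,
                 frame_size_px: Optional[int] = None):
    """Render the full synthetic movie; returns ``(MovieStack, GroundTruth)``.

    With ``read_noise_sd = 0`` and ``shot_noise_gain = 0`` the movie equals
    the exact footprint x trace superposition plus background.
    """
    rng = np.random.default_rng(seed)
    size = frame_size_px if frame_size_px is not None else 128
    n_frames = session.n_frames
    kernel = gcamp_kernel(pop.rise_s, pop.decay_s, session.frame_rate_hz)

    classes = build_population(pop, rng)
    footprints, all_onsets, all_amps = [], [], []
    traces = np.zeros((len(classes), n_frames))
    for k, dclass in enumerate(classes):
        fp = make_footprint(
            size,
            orientation=float(rng.uniform(0, np.pi)),
            length_px=min(float(rng.uniform(*pop.footprint_length_px)),
                          0.65 * size),
            branch_count=int(rng.integers(0, pop.max_branches + 1)),
            seed=int(rng.integers(0, 2 ** 31)),
        )
        onsets, amps = place_events(session, dclass, pop, rng)
        footprints.append(fp)
        all_onsets.append(onsets)
        all_amps.append(amps)
        traces[k] = pop.signal_counts * events_to_trace(
            onsets, amps, kernel, n_frames, session.frame_rate_hz)

    # smooth multiplicative background pattern around the baseline level
    rough = rng.standard_normal((size, size))
    pattern = gaussian_filter(rough, sigma=size / 8.0)
    pattern = (pattern - pattern.min()) / max(float(np.ptp(pattern)), 1e-12)
    bg_image = pop.baseline_counts * (0.8 + 0.4 * pattern)
    tgrid = session.frame_times_s
    bg_trace = 1.0 + 0.03 * np.sin(2 * np.pi * tgrid / 300.0 + rng.uniform(0, 2 * np.pi))

    A = np.stack([fp.ravel() for fp in footprints], axis=1)  # pixels x K
    movie = (A @ traces).T.reshape(n_frames, size, size)
    movie += bg_image[None, :, :] * bg_trace[:, None, None]

    if pop.read_noise_sd > 0 or pop.shot_noise_gain > 0:
        var = pop.read_noise_sd ** 2 + pop.shot_noise_gain * np.clip(movie, 0, None)
        movie = movie + np.sqrt(var) * rng.standard_normal(movie.shape)
        movie = np.clip(movie, 0.0, None)

    gt = GroundTruth(
        footprints=footprints, classes=classes,
        transient_onsets_s=all_onsets, transient_amps=all_amps,
        kernel=kernel, traces=traces,
        background_image=bg_image, background_trace=bg_trace,
    )
    return MovieStack(data=movie.astype(np.float32), frame_rate_hz=session.frame_rate_hz,
                      um_per_px=pop.um_per_px), gt
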