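"""Calcium-indicator impulse response.

A GCaMP6f-like transient is modeled as a causal double exponential
``h(t) = exp(-t/decay) - exp(-t/rise)`` with a 50-ms rise and 600-ms decay by
default.  The continuous kernel peaks at
``t* = ln(decay/rise) * rise * decay / (decay - rise)``.  Sampling at a frame
rate integrates the continuous kernel over each frame bin (so a 4-Hz kernel
is the 250-ms bin average, not a point sample) and then peak-normalizes.
"""

from __future__ import annotations

import math

import numpy as np

from ..errors import ConfigError

__all__ = ["gcamp_kernel", "kernel_peak_time"]

_FINE_DT = 1e-3


def kernel_peak_time(rise_s: float, decay_s: float) -> float:
    """Closed-form peak time of the continuous double-exponential kernel."""
    return math.log(decay_s / rise_s) * rise_s * decay_s / (decay_s - rise_s)


def gcamp_kernel(rise_s: float = 0.05, decay_s: float = 0.6,
                 frame_rate_hz: float = 4.0) -> np.ndarray:
    """Sampled, causal, peak-normalized calcium impulse response.

    The kernel starts at t = 0 (strictly zero before it) and is truncated once
    the continuous response has decayed to <0.1% of its peak.
    """
    if not (0.0 < rise_s < decay_s):
        raise ConfigError(f"need 0 < rise_s < decay_s, got {rise_s}, {decay_s}")
    if frame_rate_hz <= 0:
        raise ConfigError("frame_rate_hz must be positive")
    t_end = decay_s * 8.0
    dt = 1.0 / frame_rate_hz
    n_bins = int(math.ceil(t_end / dt))
    fine_per_bin = max(1, int(round(dt / _FINE_DT)))
    tf = (np.arange(n_bins * fine_per_bin) + 0.5) * (dt / fine_per_bin)
    h = np.exp(-tf / decay_s) - np.exp(-tf / rise_s)
    binned = h.reshape(n_bins, fine_per_bin).mean(axis=1)
    binned = np.clip(binned, 0.0, None)
    return binned / binned.max()
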