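"""Synthetic dendritic footprints.

Apical tuft dendrites imaged in layer 1 appear as elongated, gently curved,
sometimes branched structures spanning >100 um.  A footprint here is a
nonnegative weight image: a quadratic Bezier spine (plus optional branches)
rasterized and blurred to a ~2-px width, peak-normalized to 1.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from ..errors import ConfigError

__all__ = ["make_footprint", "footprint_extent"]


def _bezier(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2


def make_footprint(frame_size_px: int, orientation: float, length_px: float,
                   branch_count: int, seed: int, width_px: float = 2.0) -> np.ndarray:
    """Render one dendrite footprint.

    Parameters
    ----------
    orientation : angle of the main spine in radians.
    length_px : guaranteed lower bound on the spatial extent (max pairwise
        nonzero-pixel distance) of the result.
    """
    if length_px < 2:
        raise ConfigError(f"length_px must be >= 2, got {length_px}")
    rng = np.random.default_rng(seed)
    margin = 2.0
    chord = 1.02 * length_px
    direction = np.array([math.cos(orientation), math.sin(orientation)])
    half = 0.5 * chord * np.abs(direction)
    lo = margin + half
    hi = frame_size_px - 1 - margin - half
    if np.any(hi < lo):
        raise ConfigError(
            f"length_px={length_px} at orientation {orientation:.2f} rad does not "
            f"fit a {frame_size_px}x{frame_size_px} frame")
    center = np.array([rng.uniform(lo[0], hi[0]), rng.uniform(lo[1], hi[1])])
    p0 = center - 0.5 * chord * direction
    p2 = center + 0.5 * chord * direction
    perp = np.array([-direction[1], direction[0]])
    ctrl = 0.5 * (p0 + p2) + perp * rng.uniform(-0.1, 0.1) * chord

    n_pts = max(8, int(4 * chord))
    pts = [_bezier(p0, ctrl, p2, n_pts)]
    for _ in range(branch_count):
        t0 = rng.uniform(0.2, 0.8)
        base = (1 - t0) ** 2 * p0 + 2 * (1 - t0) * t0 * ctrl + t0 ** 2 * p2
        ang = orientation + rng.choice([-1, 1]) * rng.uniform(0.5, 1.2)
        blen = rng.uniform(0.2, 0.45) * length_px
        bdir = np.array([math.cos(ang), math.sin(ang)])
        bend = base + blen * bdir
        bctrl = base + 0.5 * blen * bdir + perp * rng.uniform(-0.05, 0.05) * blen
        pts.append(_bezier(base, bctrl, bend, max(4, int(4 * blen))))
    coords = np.concatenate(pts, axis=0)
    coords = np.clip(coords, 0, frame_size_px - 1)

    img = np.zeros((frame_size_px, frame_size_px))
    rr = np.clip(np.round(coords[:, 1]).astype(int), 0, frame_size_px - 1)
    cc = np.clip(np.round(coords[:, 0]).astype(int), 0, frame_size_px - 1)
    img[rr, cc] = 1.0
    img = gaussian_filter(img, sigma=width_px / 2.0)
    img[img < 0.05 * img.max()] = 0.0
    return img / img.max()


def footprint_extent(img: np.ndarray) -> float:
    """Maximum pairwise distance between nonzero pixels (in px)."""
    ys, xs = np.nonzero(img)
    if len(ys) < 2:
        return 0.0
    pts = np.column_stack([xs, ys]).astype(float)
    if len(pts) > 10:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear point sets
            pass
    return float(pdist(pts).max())
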