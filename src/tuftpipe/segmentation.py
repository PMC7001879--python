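"""Sparse non-negative matrix factorization of calcium movies.

The movie ``Y`` (pixels x frames) is modeled as ``Y ~ A C + b f`` with
nonnegative spatial footprints ``A`` (pixels x K), temporal traces ``C``
(K x frames) and a rank-1 background ``b f`` that absorbs the baseline and
slow drift.  The objective

    0.5 * ||Y - A C - b f||_F^2 + lambda * sum_i ||A_i||_1

is minimized by HALS (hierarchical alternating least squares): exact
coordinate minimization column by column with projection to nonnegativity,
which makes the recorded objective non-increasing at every iteration.
Because footprints are not forced to be disjoint, pixels may belong to
several components — the factorization is an overlapping clustering of
pixels by temporal covariance.  After convergence, components with too few
pixels are pruned and highly temporally correlated, spatially overlapping
components are merged; footprints are max-normalized (traces rescaled
inversely) to fix the scale indeterminacy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter, label as cc_label
from scipy.optimize import linear_sum_assignment

from .errors import ConfigError, DegenerateInputError
from .synthdata.render import GroundTruth, MovieStack

__all__ = ["SegmentationConfig", "FactorizationResult",
           "initialize_components", "factorize", "match_to_ground_truth"]


@dataclass
class SegmentationConfig:
    """Knobs of the factorization.

    ``K`` may over-specify the true source count by up to ~1.5x; pruning and
    merging bring the retained count back down.  ``sparsity_weight`` is
    dimensionless: the effective L1 penalty on footprint column k is
    ``sparsity_weight * sigma * ||C_k||`` with ``sigma`` the movie's
    estimated per-pixel noise SD, so a pixel survives only if its weight
    exceeds roughly ``sparsity_weight`` noise standard errors (the default
    was chosen by a footprint-recovery grid on synthetic movies).
    """

    K: int = 30
    sparsity_weight: float = 1.0
    max_iter: int = 60
    rel_tol: float = 1e-4
    merge_corr_threshold: float = 0.85
    merge_overlap_frac: float = 0.10
    min_footprint_px: int = 20
    background: bool = True
    init_smooth_sigma_px: float = 1.5
    init_patch_half_px: int = 40
    init_corr_threshold: float = 0.3
    # footprints may only grow within this dilation of their initial support
    # (0 disables the constraint)
    support_dilation_px: int = 6

    def validate(self) -> None:
        if self.K < 1:
            raise ConfigError("K must be >= 1")
        if self.rel_tol <= 0:
            raise ConfigError("rel_tol must be positive")
        if self.sparsity_weight < 0:
            raise ConfigError("sparsity_weight must be >= 0")


@dataclass
class FactorizationResult:
    """Footprints, traces and background of one factorized movie."""

    A: np.ndarray                  # pixels x K
    C: np.ndarray                  # K x frames
    b: np.ndarray                  # pixels
    f: np.ndarray                  # frames
    objective_history: np.ndarray  # per-iteration objective (non-increasing)
    frame_shape: tuple
    converged: bool = True

    @property
    def n_components(self) -> int:
        return self.A.shape[1]

    def footprint_image(self, k: int) -> np.ndarray:
        return self.A[:, k].reshape(self.frame_shape)

    def reconstruction(self) -> np.ndarray:
        return self.A @ self.C + np.outer(self.b, self.f)


def _as_matrix(stack: MovieStack) -> np.ndarray:
    return stack.data.reshape(stack.n_frames, -1).T.astype(np.float64)


def initialize_components(stack: MovieStack, cfg: SegmentationConfig,
                          seed: int = 0):
    """Greedy rank-1 seeding.

    Iteratively picks the pixel whose spatially smoothed, mean-subtracted
    trace explains the most residual variance, takes its local correlation
    patch as the footprint seed, and subtracts the rank-1 explanation.  The
    background initializes from the pixelwise temporal median and the
    normalized frame mean.  The seed only breaks exact variance ties.
    """
    cfg.validate()
    H, W = stack.frame_shape
    n_px = H * W
    if cfg.K > n_px:
        raise ConfigError("K exceeds the pixel count")
    Y = _as_matrix(stack)  # pixels x T
    if float(Y.var()) == 0.0:
        raise DegenerateInputError("movie has zero variance")

    rng = np.random.default_rng(seed)
    sm = gaussian_filter(stack.data.astype(np.float64),
                         sigma=(0, cfg.init_smooth_sigma_px, cfg.init_smooth_sigma_px))
    R = sm.reshape(stack.n_frames, -1).T
    R = R - R.mean(axis=1, keepdims=True)
    Ymean = Y.mean(axis=1)

    A0 = np.zeros((n_px, cfg.K))
    C0 = np.zeros((cfg.K, stack.n_frames))
    half = cfg.init_patch_half_px
    for k in range(cfg.K):
        var = np.einsum("ij,ij->i", R, R)
        best = float(var.max())
        if best <= 0:
            break
        ties = np.where(var >= best * (1 - 1e-12))[0]
        p = int(rng.choice(ties)) if len(ties) > 1 else int(ties[0])
        c = R[p].copy()
        cnorm = float(c @ c)
        py, px = divmod(p, W)
        y0, y1 = max(0, py - half), min(H, py + half + 1)
        x0, x1 = max(0, px - half), min(W, px + half + 1)
        box = (np.arange(y0, y1)[:, None] * W + np.arange(x0, x1)[None, :]).ravel()
        patch = R[box]
        coef_sm = patch @ c / cnorm
        # footprint weights from the unsmoothed movie so the seed is not
        # spatially blurred; the smoothed patch only builds the mask
        raw = Y[box] - Ymean[box, None]
        coef = raw @ c / cnorm
        norms = np.sqrt(np.einsum("ij,ij->i", patch, patch))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (patch @ c) / (norms * np.sqrt(cnorm))
        corr = np.nan_to_num(corr).reshape(y1 - y0, x1 - x0)
        mask = corr > cfg.init_corr_threshold
        # keep only the correlated region connected to the seed pixel, so a
        # co-active but spatially separate structure is not swept in
        labels, _ = cc_label(mask)
        seed_lab = labels[py - y0, px - x0]
        if seed_lab > 0:
            mask &= labels == seed_lab
        else:
            mask[py - y0, px - x0] = True
        a = np.where(mask.ravel(), np.clip(coef, 0, None), 0.0)
        if a.max() <= 0:
            a[np.searchsorted(box, p)] = 1.0
        A0[box, k] = a
        C0[k] = np.clip(c, 0, None)
        # subtract the full rank-1 explanation (not just the masked seed) so
        # the same source does not keep attracting later seeds
        R[box] -= np.outer(np.clip(coef_sm, 0, None), c)

    b0 = np.median(Y, axis=1)
    f_raw = Y.mean(axis=0)
    f0 = f_raw / max(float(f_raw.mean()), 1e-12)
    return A0, C0, b0, f0


def _objective(yss: float, Ab: np.ndarray, Cb: np.ndarray, Q: np.ndarray,
               pen: np.ndarray) -> float:
    # Q = Y @ Cb.T with current Cb; yss = ||Y||_F^2
    G = Ab.T @ Ab
    H = Cb @ Cb.T
    resid = yss - 2.0 * float(np.sum(Ab * Q)) + float(np.sum(G * H))
    return 0.5 * resid + float(pen @ Ab.sum(axis=0))


def _noise_sd(Y: np.ndarray, rng: np.random.Generator, n_sample: int = 2000) -> float:
    """Robust per-pixel noise SD from first temporal differences."""
    idx = rng.choice(Y.shape[0], size=min(n_sample, Y.shape[0]), replace=False)
    d = np.diff(Y[idx], axis=1)
    return float(np.median(np.abs(d)) / (0.6745 * math.sqrt(2.0)))


def factorize(stack: MovieStack, cfg: SegmentationConfig, seed: int = 0,
              init=None) -> FactorizationResult:
    """Run the sparse NMF to convergence (or ``max_iter``).

    Non-convergence is reported through ``converged=False``, never raised.
    """
    cfg.validate()
    Y = _as_matrix(stack)
    if init is None:
        A0, C0, b0, f0 = initialize_components(stack, cfg, seed=seed)
    else:
        A0, C0, b0, f0 = init
    K = A0.shape[1]

    if cfg.background:
        Ab = np.column_stack([A0, b0]).astype(np.float64)
        Cb = np.vstack([C0, f0[None, :]]).astype(np.float64)
    else:
        Ab = A0.astype(np.float64).copy()
        Cb = C0.astype(np.float64).copy()
    n_comp = Ab.shape[1]
    yss = float(np.einsum("ij,ij->", Y, Y))

    # L1 penalty per component, frozen at initialization so the objective is
    # a fixed function: lambda * sigma * ||C0_k|| (no penalty on background)
    sigma = _noise_sd(Y, np.random.default_rng(seed))
    cnorms = np.sqrt(np.einsum("ij,ij->i", Cb[:K], Cb[:K]))
    floor = max(float(np.median(cnorms[cnorms > 0])) if (cnorms > 0).any() else 1.0,
                1e-9)
    cnorms[cnorms <= 0] = floor
    pen = np.zeros(n_comp)
    pen[:K] = cfg.sparsity_weight * sigma * cnorms

    # spatial support constraint: each footprint may only occupy a dilated
    # neighborhood of its initial support (background is unconstrained)
    support = None
    if cfg.support_dilation_px > 0:
        H, W = stack.frame_shape
        support = np.empty((Y.shape[0], K), dtype=bool)
        for k in range(K):
            m = (A0[:, k] > 0).reshape(H, W)
            if not m.any():
                support[:, k] = True
                continue
            support[:, k] = binary_dilation(
                m, iterations=cfg.support_dilation_px).ravel()

    history = []
    converged = False
    for it in range(cfg.max_iter):
        # C update (background row included, no penalty)
        G = Ab.T @ Ab
        P = Ab.T @ Y
        for k in range(n_comp):
            denom = G[k, k]
            if denom <= 1e-12:
                continue
            Cb[k] = np.clip(Cb[k] + (P[k] - G[k] @ Cb) / denom, 0.0, None)
        # A update (L1 penalty on the K component columns only)
        Hm = Cb @ Cb.T
        Q = Y @ Cb.T
        for k in range(n_comp):
            denom = Hm[k, k]
            if denom <= 1e-12:
                continue
            Ab[:, k] = np.clip(Ab[:, k] + (Q[:, k] - Ab @ Hm[:, k] - pen[k]) / denom,
                               0.0, None)
            if support is not None and k < K:
                Ab[~support[:, k], k] = 0.0
        obj = _objective(yss, Ab, Cb, Q, pen)
        history.append(obj)
        if it > 0:
            prev = history[-2]
            if prev > 0 and abs(prev - obj) / prev < cfg.rel_tol:
                converged = True
                break

    if cfg.background:
        A, C = Ab[:, :K], Cb[:K]
        b, f = Ab[:, K].copy(), Cb[K].copy()
    else:
        A, C = Ab, Cb
        b = np.zeros(Y.shape[0])
        f = np.zeros(Y.shape[1])

    A, C = _prune(A, C, cfg.min_footprint_px)
    A, C = _merge(A, C, cfg.merge_corr_threshold, cfg.merge_overlap_frac)
    A, C = _normalize(A, C)
    return FactorizationResult(A=A, C=C, b=b, f=f,
                               objective_history=np.asarray(history),
                               frame_shape=stack.frame_shape, converged=converged)


def _prune(A, C, min_px):
    keep = (A > 0).sum(axis=0) >= min_px
    if not keep.any():  # keep the largest rather than return nothing
        keep[np.argmax((A > 0).sum(axis=0))] = True
    return A[:, keep], C[keep]


def _merge(A, C, corr_thr, overlap_frac):
    """Union-find merge of temporally correlated, spatially overlapping pairs."""
    K = A.shape[1]
    if K <= 1:
        return A, C
    Cc = C - C.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", Cc, Cc))
    norms[norms == 0] = 1.0
    corr = (Cc @ Cc.T) / np.outer(norms, norms)
    nz = A > 0
    counts = nz.sum(axis=0)
    parent = list(range(K))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(K):
        for j in range(i + 1, K):
            if corr[i, j] <= corr_thr:
                continue
            shared = int(np.count_nonzero(nz[:, i] & nz[:, j]))
            if shared > overlap_frac * max(1, min(counts[i], counts[j])):
                parent[find(i)] = find(j)

    groups: dict = {}
    for i in range(K):
        groups.setdefault(find(i), []).append(i)
    if len(groups) == K:
        return A, C
    newA = np.zeros((A.shape[0], len(groups)))
    newC = np.zeros((len(groups), C.shape[1]))
    for g, members in enumerate(groups.values()):
        newA[:, g] = A[:, members].sum(axis=1)
        w = np.array([C[m].var() for m in members])
        w = w / w.sum() if w.sum() > 0 else np.full(len(members), 1 / len(members))
        newC[g] = w @ C[members]
    return newA, newC


def _normalize(A, C):
    """Max-normalize footprints, rescale traces; A @ C is unchanged."""
    scale = A.max(axis=0)
    scale[scale == 0] = 1.0
    return A / scale, C * scale[:, None]


def match_to_ground_truth(result: FactorizationResult, gt: GroundTruth) -> dict:
    """Optimal one-to-one spatial matching of components to planted footprints.

    Maximizes summed cosine similarity (Hungarian assignment).  Returns a dict
    with a per-pair table and the unmatched index lists.
    """
    comps = result.A
    truth = np.stack([fp.ravel() for fp in gt.footprints], axis=1)
    if comps.shape[0] != truth.shape[0]:
        raise ConfigError("frame geometry differs between result and ground truth")

    def _unit(M):
        n = np.linalg.norm(M, axis=0)
        n[n == 0] = 1.0
        return M / n

    S = _unit(comps).T @ _unit(truth)  # components x truth
    rows, cols = linear_sum_assignment(-S)
    pairs = pd.DataFrame({
        "component": rows,
        "gt_index": cols,
        "cosine": S[rows, cols],
    })
    return {
        "pairs": pairs,
        "unmatched_components": sorted(set(range(comps.shape[1])) - set(rows)),
        "unmatched_ground_truth": sorted(set(range(truth.shape[1])) - set(cols)),
    }
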