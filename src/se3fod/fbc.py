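"""Fiber-to-bundle coherence (FBC): scoring and filtering spurious fibers.

Every oriented streamline point is treated as a delta distribution on
R^3 x S^2 (with both +-tangent orientations, since diffusion MRI cannot
distinguish them).  Diffusing this density with the contour-enhancement
kernel and evaluating it back at the fiber points gives the *local* FBC:
points isolated from, or badly aligned with, the rest of the tractogram
receive low density.  Per fiber:

* FBC        — mean LFBC along the fiber,
* FBC^alpha  — minimum over windows of alpha points of the window mean
               (spuriousness is often local),
* AFBC       — bundle average of FBC,
* RFBC       — FBC^alpha / AFBC, the relative coherence used for filtering:
               fibers with RFBC below a fraction of the maximum RFBC are
               removed.

Default kernel parameters D33 = 1, D44 = 0.04, t = 1.4 (spatial units =
the streamline coordinate units, normally mm).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import cKDTree

from se3fod.bundles import FiberBundle
from se3fod.kernel import EnhancementParams, kernel_3d
from se3fod.sphere import rotation_to

logger = logging.getLogger(__name__)

FBC_DEFAULT_PARAMS = EnhancementParams(d33=1.0, d44=0.04, t=1.4)


def spatial_cutoff_radius(
    params: EnhancementParams, relative_floor: float = 1e-6
) -> float:
    """Distance beyond which the kernel is below ``relative_floor`` of its max.

    The slowest spatial decay is along the orientation axis, where the
    kernel falls off as exp(-z^2 / (16 D33 t)).
    """
    return 4.0 * np.sqrt(params.d33 * params.t * np.log(1.0 / relative_floor))


class LFBCProfile:
    """Per-fiber, per-point nonnegative LFBC values."""

    def __init__(self, values: list, params: EnhancementParams):
        self.values = values  # list of (N_i,) arrays
        self.params = params
        for v in values:
            if np.any(v < 0):
                raise ValueError("LFBC values must be nonnegative")

    def __getitem__(self, i: int) -> np.ndarray:
        return self.values[i]

    @property
    def n_fibers(self) -> int:
        return len(self.values)


def compute_lfbc(
    bundle: FiberBundle,
    params: EnhancementParams = FBC_DEFAULT_PARAMS,
    spatial_cutoff: float | None = None,
    exact: bool = False,
    chunk: int = 256,
) -> LFBCProfile:
    """Local fiber-to-bundle coherence at every fiber point.

        LFBC(p_k) = (1/N_tot) sum_{sigma=+-} sum_q
                    p_t(R_{sigma n_q}^T (y_k - y_q), R_{sigma n_q}^T n_k)

    The sum runs over *all* oriented source points q including the point
    itself (the self term adds the same kernel-at-origin offset to every
    point).  Source pairs farther than the spatial cutoff (where the
    kernel is below 1e-6 of its maximum) are skipped unless ``exact``.
    """
    if bundle.n_fibers == 0:
        raise ValueError("empty bundle")
    pts = bundle.all_points()
    tans = bundle.all_tangents()
    N = pts.shape[0]
    if spatial_cutoff is None:
        spatial_cutoff = spatial_cutoff_radius(params)

    R = rotation_to(tans)  # (N, 3, 3), R e_z = n
    flip = np.array([1.0, -1.0, -1.0])  # R_{-n} = R_n @ Rx(pi)

    tree = cKDTree(pts) if not exact else None
    lfbc = np.zeros(N)
    n_pairs = n_skipped = 0
    for start in range(0, N, chunk):
        sl = slice(start, min(start + chunk, N))
        tgt_p = pts[sl]
        tgt_n = tans[sl]
        if exact:
            src_lists = [np.arange(N)] * tgt_p.shape[0]
        else:
            src_lists = tree.query_ball_point(tgt_p, spatial_cutoff)
        for k, src in enumerate(src_lists):
            src = np.asarray(src, dtype=int)
            n_pairs += src.size
            n_skipped += N - src.size
            rel = tgt_p[k] - pts[src]                     # (S, 3)
            Rs = R[src]
            local_y = np.einsum("sa,sab->sb", rel, Rs)    # R^T (y_k - y_q)
            local_n = np.einsum("a,sab->sb", tgt_n[k], Rs)
            val = kernel_3d(local_y, local_n, params)
            val = val + kernel_3d(local_y * flip, local_n * flip, params)
            lfbc[start + k] = val.sum()
    lfbc /= bundle.n_total
    frac = n_skipped / max(n_pairs + n_skipped, 1)
    logger.info(
        "LFBC: %d points, cutoff %.1f, skipped pair fraction %.3f",
        N, spatial_cutoff, frac,
    )
    values = [lfbc[s] for s in bundle.fiber_slices()]
    return LFBCProfile(values, params)


def fbc_full(profile: LFBCProfile, fiber_index: int) -> float:
    """FBC of one fiber: mean LFBC over its (uniform-arclength) points."""
    return float(np.mean(profile[fiber_index]))


def fbc_alpha(profile: LFBCProfile, fiber_index: int, alpha_points: int) -> float:
    """Windowed-minimum FBC: min over alpha-point windows of the window mean."""
    v = profile[fiber_index]
    n = v.shape[0]
    if not (1 <= alpha_points <= n):
        raise ValueError(f"alpha_points must be in [1, {n}]")
    csum = np.concatenate([[0.0], np.cumsum(v)])
    windows = (csum[alpha_points:] - csum[:-alpha_points]) / alpha_points
    return float(windows.min())


def afbc(profile: LFBCProfile) -> float:
    """Average FBC over fibers (each fiber weighted equally)."""
    return float(np.mean([fbc_full(profile, i) for i in range(profile.n_fibers)]))


def rfbc(
    bundle: FiberBundle,
    params: EnhancementParams = FBC_DEFAULT_PARAMS,
    alpha_points: int | None = None,
    alpha_mm: float | None = None,
    profile: LFBCProfile | None = None,
    **lfbc_kwargs,
) -> np.ndarray:
    """Relative FBC score per fiber: FBC^alpha / AFBC.

    ``alpha`` may be given in points or in mm (converted via each fiber's
    step and clipped to its point count).  Scores are nonnegative; low
    scores flag spurious fibers.
    """
    if profile is None:
        profile = compute_lfbc(bundle, params, **lfbc_kwargs)
    denom = afbc(profile)
    if denom <= 0:
        raise RuntimeError("degenerate bundle: AFBC is zero")
    scores = np.empty(bundle.n_fibers)
    for i in range(bundle.n_fibers):
        n_i = profile[i].shape[0]
        if alpha_points is not None:
            a = min(alpha_points, n_i)
        elif alpha_mm is not None:
            a = int(np.clip(round(alpha_mm / bundle.fibers[i].step), 1, n_i))
        else:
            a = n_i
        scores[i] = fbc_alpha(profile, i, a) / denom
    return scores


def filter_bundle(
    bundle: FiberBundle, scores: np.ndarray, epsilon_fraction: float
) -> FiberBundle:
    """Retain fibers with RFBC >= epsilon_fraction * max(RFBC).

    The argmax fiber always survives, so the result is nonempty.
    """
    if not (0.0 <= epsilon_fraction <= 1.0):
        raise ValueError("epsilon_fraction must be in [0, 1]")
    scores = np.asarray(scores, dtype=float)
    eps = epsilon_fraction * scores.max()
    keep = np.where(scores >= eps)[0]
    return bundle.subset(keep)


def ml_tp_distance(filtered: FiberBundle, target_point) -> float:
    """Distance from the closest fiber point to a target (e.g. temporal pole)."""
    if filtered.n_fibers == 0:
        raise ValueError("empty bundle")
    pts = filtered.all_points()
    return float(np.min(np.linalg.norm(pts - np.asarray(target_point, float), axis=1)))
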