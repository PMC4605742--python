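"""Deterministic and probabilistic streamline tractography on SH FOD fields.

Streamlines are integrated with a fixed step of 1/10th of the voxel size.
Deterministic tracking follows the FOD peak most aligned with the incoming
direction and stops when that peak falls below 10% of the voxel's maximal
angular response.  Probabilistic tracking samples the next direction from
the positive FOD amplitudes restricted to the curvature cone implied by a
minimal radius of curvature (1 mm by default).  The initial direction must
be a near-maximal peak (initial cutoff 0.9).

Directions are discretized on an icosphere tessellation (frequency >= 8 for
probabilistic sampling), which makes runs exactly reproducible under a
fixed seed.  SH coefficients are interpolated trilinearly at off-grid
positions.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np

from se3fod.bundles import FiberBundle, Streamline
from se3fod.enhance import SHField
from se3fod.sphere import SphereSampling, cached_icosphere, sh_basis_matrix

logger = logging.getLogger(__name__)


@dataclass
class TrackingConfig:
    step_fraction: float = 0.1      # of voxel size
    cutoff: float = 0.1             # relative FOD termination threshold
    init_cutoff: float = 0.9        # relative threshold for initial peak
    min_radius: float = 1.0         # mm, probabilistic curvature bound
    min_length: float = 0.0         # mm
    max_count: int = 10000
    max_steps: int = 10000
    rng_seed: int = 0
    sampling_frequency: int = 16

    def __post_init__(self):
        if not (0.0 < self.cutoff <= self.init_cutoff <= 1.0):
            raise ValueError("need 0 < cutoff <= init_cutoff <= 1")
        if self.step_fraction <= 0 or self.min_radius <= 0:
            raise ValueError("step_fraction and min_radius must be positive")

    def max_turning_angle(self, step: float) -> float:
        """Per-step turning bound 2 arcsin(step / (2 r_min))."""
        return 2.0 * np.arcsin(min(1.0, step / (2.0 * self.min_radius)))


def find_peaks(
    values: np.ndarray,
    sampling: SphereSampling,
    relative_threshold: float = 0.1,
    absolute_threshold: float | None = None,
):
    """Local maxima of a function on the tessellation.

    A direction is a peak iff its value strictly exceeds all mesh
    neighbors and exceeds ``relative_threshold`` times the global maximum
    (or ``absolute_threshold`` if given).  One representative per
    antipodal pair is returned (the one with larger index wins ties by
    symmetry; pairs tie exactly for symmetric input).

    Returns ``(directions, amplitudes)`` sorted by descending amplitude.
    """
    values = np.asarray(values, dtype=float)
    vmax = float(values.max()) if values.size else 0.0
    if vmax <= 0:
        return np.empty((0, 3)), np.empty(0)
    thr = (
        absolute_threshold
        if absolute_threshold is not None
        else relative_threshold * vmax
    )
    nbr, mask = _neighbor_matrix(sampling)
    nvals = np.where(mask, values[nbr], -np.inf)
    is_peak = (values > nvals.max(axis=1)) & (values > thr)
    idx = np.where(is_peak)[0]
    # one representative per antipodal pair
    keep = idx[idx <= sampling.antipodal_index[idx]]
    # antipodally symmetric input peaks in pairs; recover lone survivors
    lone = idx[
        (idx > sampling.antipodal_index[idx])
        & ~is_peak[sampling.antipodal_index[idx]]
    ]
    keep = np.concatenate([keep, sampling.antipodal_index[lone]])
    order = np.argsort(values[keep])[::-1]
    keep = keep[order]
    return sampling.directions[keep], values[keep]


def _neighbor_matrix(sampling: SphereSampling):
    """Padded neighbor-index matrix with validity mask (cached)."""
    if "nbr_matrix" not in sampling._cache:
        nb = sampling.neighbors
        width = max(len(a) for a in nb)
        mat = np.zeros((sampling.n_directions, width), dtype=int)
        mask = np.zeros((sampling.n_directions, width), dtype=bool)
        for i, a in enumerate(nb):
            mat[i, : len(a)] = a
            mask[i, : len(a)] = True
        sampling._cache["nbr_matrix"] = (mat, mask)
    return sampling._cache["nbr_matrix"]


class _FieldInterpolator:
    """Trilinear interpolation of SH coefficients + amplitude evaluation."""

    def __init__(self, field: SHField, sampling: SphereSampling):
        self.coef = field.coefficients
        self.spacing = np.asarray(field.voxel_size, dtype=float)
        self.shape = np.array(field.grid_shape)
        self.B = sh_basis_matrix(field.basis, sampling)  # (M, C)
        self.sampling = sampling

    def inside(self, pos: np.ndarray) -> bool:
        idx = pos / self.spacing
        return bool(np.all(idx >= 0.0) and np.all(idx <= self.shape - 1))

    def coefficients_at(self, pos: np.ndarray) -> np.ndarray:
        idx = pos / self.spacing
        base = np.floor(idx).astype(int)
        base = np.clip(base, 0, self.shape - 2)
        frac = idx - base
        c = 0.0
        for cx in (0, 1):
            wx = frac[0] if cx else 1.0 - frac[0]
            for cy in (0, 1):
                wy = frac[1] if cy else 1.0 - frac[1]
                for cz in (0, 1):
                    wz = frac[2] if cz else 1.0 - frac[2]
                    w = wx * wy * wz
                    if w:
                        c = c + w * self.coef[base[0] + cx, base[1] + cy, base[2] + cz]
        return c

    def amplitudes_at(self, pos: np.ndarray) -> np.ndarray:
        return self.B @ self.coefficients_at(pos)

    @property
    def voxel_max(self) -> np.ndarray:
        """Per-voxel maximal angular response (computed once, cached)."""
        if not hasattr(self, "_voxel_max"):
            flat = self.coef.reshape(-1, self.coef.shape[-1])
            vm = np.empty(flat.shape[0])
            chunk = 4096
            for s in range(0, flat.shape[0], chunk):
                vm[s : s + chunk] = (flat[s : s + chunk] @ self.B.T).max(axis=1)
            self._voxel_max = vm.reshape(self.coef.shape[:3])
        return self._voxel_max

    def voxel_max_at(self, pos: np.ndarray) -> float:
        idx = np.clip(
            np.floor(pos / self.spacing + 0.5).astype(int), 0, self.shape - 1
        )
        return float(self.voxel_max[tuple(idx)])

    def cone_members(self, cone_cos: float) -> list:
        """Direction indices within the curvature cone of each direction."""
        key = ("cone", round(cone_cos, 12), self.sampling.frequency)
        if key not in self.sampling._cache:
            dots = self.sampling.directions @ self.sampling.directions.T
            self.sampling._cache[key] = [
                np.where(dots[i] >= cone_cos - 1e-12)[0]
                for i in range(self.sampling.n_directions)
            ]
        return self.sampling._cache[key]


def _seed_rng(config: TrackingConfig, seed_point: np.ndarray):
    """Per-seed RNG keyed by the seed's coordinates, not its list position."""
    h = zlib.crc32(np.round(np.asarray(seed_point, float), 9).tobytes())
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(h,))
    )


def _grow(interp, start, direction, step, config, deterministic, cone_cos, rng):
    """March one half-streamline; returns points beyond the seed."""
    pts = []
    pos = start.copy()
    d = direction / np.linalg.norm(direction)
    dirs = interp.sampling.directions
    w = interp.sampling.weights
    if not deterministic:
        cones = interp.cone_members(cone_cos)
        di = int(np.argmax(dirs @ d))
        d = dirs[di]
    for _ in range(config.max_steps):
        pos = pos + step * d
        if not interp.inside(pos):
            break
        if deterministic:
            amp = interp.amplitudes_at(pos)
            vmax = float(amp.max())
            if vmax <= 0:
                break
            peak_dirs, peak_amps = find_peaks(
                amp, interp.sampling, relative_threshold=config.cutoff
            )
            if len(peak_amps) == 0:
                break
            align = np.abs(peak_dirs @ d)
            best = int(np.argmax(align))
            if peak_amps[best] < config.cutoff * vmax:
                break
            new_d = peak_dirs[best]
            if new_d @ d < 0:
                new_d = -new_d
            d = new_d
        else:
            vmax = interp.voxel_max_at(pos)
            if vmax <= 0:
                break
            cand = cones[di]
            amp = interp.B[cand] @ interp.coefficients_at(pos)
            p = np.maximum(amp, 0.0)
            # termination: cone-averaged positive amplitude must stay
            # above the cutoff fraction of the voxel's maximal response
            wc = w[cand]
            if float(p @ wc) / float(wc.sum()) < config.cutoff * vmax:
                break
            total = p.sum()
            if total <= 0:
                break
            di = int(rng.choice(cand, p=p / total))
            d = dirs[di]
        pts.append(pos.copy())
    return pts


def _initial_directions(interp, seed, config, rng):
    amp = interp.amplitudes_at(seed)
    vmax = float(amp.max())
    if vmax <= 0:
        return None
    peak_dirs, peak_amps = find_peaks(
        amp, interp.sampling, relative_threshold=config.cutoff
    )
    qual = peak_amps >= config.init_cutoff * vmax
    if not np.any(qual):
        return None
    pick = rng.integers(0, int(qual.sum()))
    return peak_dirs[np.where(qual)[0][pick]]


def _track(field, seeds, config, deterministic):
    sampling = cached_icosphere(config.sampling_frequency)
    interp = _FieldInterpolator(field, sampling)
    step = config.step_fraction * float(np.min(field.voxel_size))
    cone_cos = np.cos(config.max_turning_angle(step))
    fibers = []
    for seed in np.atleast_2d(np.asarray(seeds, dtype=float)):
        if len(fibers) >= config.max_count:
            break
        if not interp.inside(seed):
            logger.info("seed %s outside volume; skipped", seed)
            continue
        rng = _seed_rng(config, seed)
        d0 = _initial_directions(interp, seed, config, rng)
        if d0 is None:
            continue
        fwd = _grow(interp, seed, d0, step, config, deterministic, cone_cos, rng)
        bwd = _grow(interp, seed, -d0, step, config, deterministic, cone_cos, rng)
        pts = bwd[::-1] + [seed.copy()] + fwd
        if (len(pts) - 1) * step < config.min_length or len(pts) < 2:
            continue
        fibers.append(Streamline(points=np.array(pts), step=step))
    logger.info("tracking: %d streamlines retained", len(fibers))
    return FiberBundle(fibers=fibers) if fibers else FiberBundle(fibers=[], tangents=[])


def track_deterministic(field: SHField, seeds, config: TrackingConfig | None = None) -> FiberBundle:
    """Peak-following tractography (bidirectional from each seed)."""
    return _track(field, seeds, config or TrackingConfig(), deterministic=True)


def track_probabilistic(field: SHField, seeds, config: TrackingConfig | None = None) -> FiberBundle:
    """FOD-sampling tractography restricted to the curvature cone."""
    return _track(field, seeds, config or TrackingConfig(), deterministic=False)
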