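"""Analytic contour-enhancement kernel on R^2 x S^1 and R^3 x S^2.

Contour enhancement is the hypo-elliptic diffusion

    d/dt W = (D33 (n . grad_y)^2 + D44 Lap_{S^2}) W

on the coupled space of positions and orientations: spatial diffusion acts
only along the current orientation n, angular diffusion isotropically on the
sphere.  Its Green's function has no simple closed form; this module
implements the standard analytic approximation that factors the 3D kernel
into two planar (R^2 x S^1) contour-enhancement kernels, and discretizes it
into a mass-normalized lookup table (LUT) for shift-twist convolution.

The approximation's unnormalized prefactors are irrelevant here: the diffusion
semigroup conserves mass, so the discrete table is renormalized exactly
(see :func:`build_kernel_lut`).  Spatial units are voxels unless a scale is
applied by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from se3fod.sphere import SphereSampling, rotation_to, to_beta_gamma

logger = logging.getLogger(__name__)

_SERIES_SWITCH = np.pi / 10.0


@dataclass(frozen=True)
class EnhancementParams:
    """Diffusion parameters of the contour-enhancement PDE.

    Attributes
    ----------
    d33 : float
        Spatial diffusivity along the orientation (voxel^2 per unit time).
    d44 : float
        Angular diffusivity (rad^2 per unit time).  Both must be positive
        (the Hoermander condition for a smooth kernel).
    t : float
        Diffusion time; larger t takes more context into account.
    """

    d33: float = 1.0
    d44: float = 0.02
    t: float = 1.0

    def __post_init__(self):
        if self.d33 <= 0 or self.d44 <= 0:
            raise ValueError("d33 and d44 must be positive")
        if self.t < 0:
            raise ValueError("diffusion time t must be nonnegative")


def _stab_core(theta: np.ndarray) -> np.ndarray:
    """theta / (2 tan(theta/2)) on |theta| <= pi, series branch near 0.

    Written as (theta/2) cos(theta/2) / sin(theta/2) so that the limit 0 at
    theta = +-pi is reached exactly.
    """
    out = np.empty_like(theta)
    small = np.abs(theta) < _SERIES_SWITCH
    t2 = theta[small] ** 2
    out[small] = (
        1.0 - t2 / 12.0 - t2 ** 2 / 720.0 - t2 ** 3 / 30240.0
        - t2 ** 4 / 1209600.0
    )
    ts = theta[~small]
    out[~small] = (ts / 2.0) * np.cos(ts / 2.0) / np.sin(ts / 2.0)
    return out


def stab_factor(theta):
    """The stabilized factor theta / (2 tan(theta/2)).

    Continuous at 0 with value 1.  For |theta| < pi/10 the closed form is
    replaced by its Taylor series 1 - theta^2/12 - theta^4/720 - ... to
    avoid cancellation; the two branches agree to ~1e-12 at the switch.
    """
    theta = np.asarray(theta, dtype=float)
    scalar = theta.ndim == 0
    theta = np.atleast_1d(theta)
    if np.any(np.abs(theta) >= np.pi):
        raise ValueError("|theta| must be < pi")
    out = _stab_core(theta)
    return float(out[0]) if scalar else out


def en_distance(x, y, theta, params: EnhancementParams):
    """Squared-distance modulus EN in the exponent of the planar kernel.

    EN >= 0, vanishes at the origin, and is invariant under
    (x, y) -> (-x, -y) since every inner term is squared.
    """
    scalar = np.ndim(x) == 0 and np.ndim(y) == 0 and np.ndim(theta) == 0
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    # Wrap to [-pi, pi); the chart can deliver beta = pi (target antipodal
    # to the source), where the stabilized factor has the exact limit 0.
    theta = np.atleast_1d(
        np.mod(np.asarray(theta, dtype=float) + np.pi, 2.0 * np.pi) - np.pi
    )
    c = _stab_core(theta)
    d33, d44 = params.d33, params.d44
    term1 = (theta ** 2 / d44 + (theta * y / 2.0 + c * x) ** 2 / d33) ** 2
    term2 = (-theta * x / 2.0 + c * y) ** 2 / (d44 * d33)
    out = np.sqrt(term1 + term2)
    return float(out[0]) if scalar else out


def kernel_2d(x, y, theta, params: EnhancementParams):
    """Planar (R^2 x S^1) contour-enhancement kernel, up to normalization.

    Proportional to exp(-EN(x, y, theta) / (4 t)); maximal at the origin.
    The analytic prefactor is kept only so that values are comparable across
    evaluations with the same parameters.
    """
    if params.t <= 0:
        raise ValueError("kernel requires t > 0 (t = 0 is a delta)")
    pref = 1.0 / (32.0 * np.pi * params.t ** 2 * np.sqrt(params.d44 * params.d33))
    return pref * np.exp(-en_distance(x, y, theta, params) / (4.0 * params.t))


def kernel_3d(y, n, params: EnhancementParams):
    """Contour-enhancement kernel on R^3 x S^2, up to normalization.

    Factors into two planar kernels via the chart n = n(beta, gamma):

        p_t(y, n) ~ k2(z/2, x, beta) * k2(z/2, -y, gamma)

    with y = (x, y, z) the spatial offset in the frame of the source
    orientation (source aligned with e_z).  Axially symmetric about e_z.
    Broadcasts over leading axes of ``y`` (..., 3) and ``n`` (..., 3).
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    bg = to_beta_gamma(n)
    if hasattr(bg, "beta"):
        beta, gamma = bg.beta, bg.gamma
    else:
        beta, gamma = bg[0], bg[1]
    xs, ys, zs = y[..., 0], y[..., 1], y[..., 2]
    return kernel_2d(zs / 2.0, xs, beta, params) * kernel_2d(
        zs / 2.0, -ys, gamma, params
    )


def default_half_width(params: EnhancementParams, mass_tolerance: float = 2e-2) -> int:
    """Window half-width so that clipped spatial tail mass is small.

    The kernel's spatial marginal along the orientation axis is Gaussian
    with standard deviation 2 sqrt(D33 t); 2.3 sigma keeps the clipped mass
    around 1% while keeping the table tractable.  build_kernel_lut verifies
    the actual tail mass and raises if the window is too small for the
    requested tolerance.
    """
    sigma = 2.0 * np.sqrt(params.d33 * params.t)
    return max(2, int(np.ceil(2.3 * sigma)))


@dataclass
class KernelLUT:
    """Discretized enhancement kernel for shift-twist convolution.

    ``table[s, o, d]`` is the kernel weight from source orientation index
    ``s`` through spatial offset ``offsets[o]`` to target orientation index
    ``d``.  After construction the table is (i) symmetrized under the
    adjoint exchange (source, offset, target) -> (target, -offset, source)
    and under antipodal flips, and (ii) diagonally rescaled (symmetric
    Sinkhorn) so that the quadrature mass of every source slice *and* every
    target slice is exactly 1.  The first property makes the discrete
    convolution mass-preserving; the second makes it exact on constants.
    """

    params: EnhancementParams
    sampling: SphereSampling
    half_width: int
    offsets: np.ndarray  # (K, 3) int voxel offsets
    table: np.ndarray    # (M, K, M) float

    @property
    def n_offsets(self) -> int:
        return self.offsets.shape[0]

    def canonical_slice(self, direction_index: int) -> np.ndarray:
        """Kernel slice (offsets x orientations) for one source orientation."""
        return self.table[direction_index]

    def save(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["d33"] = self.params.d33
            f.attrs["d44"] = self.params.d44
            f.attrs["t"] = self.params.t
            f.attrs["half_width"] = self.half_width
            f.attrs["frequency"] = self.sampling.frequency
            f.create_dataset("offsets", data=self.offsets)
            f.create_dataset("table", data=self.table)

    @classmethod
    def load(cls, path: str) -> "KernelLUT":
        import h5py

        from se3fod.sphere import cached_icosphere

        with h5py.File(path, "r") as f:
            params = EnhancementParams(
                d33=float(f.attrs["d33"]),
                d44=float(f.attrs["d44"]),
                t=float(f.attrs["t"]),
            )
            sampling = cached_icosphere(int(f.attrs["frequency"]))
            return cls(
                params=params,
                sampling=sampling,
                half_width=int(f.attrs["half_width"]),
                offsets=f["offsets"][...],
                table=f["table"][...],
            )


def _raw_table(
    params: EnhancementParams, sampling: SphereSampling, offsets: np.ndarray
) -> np.ndarray:
    """Evaluate p_t(R_s^T d, R_s^T n) for all (source, offset, target)."""
    dirs = sampling.directions
    M, K = dirs.shape[0], offsets.shape[0]
    R = rotation_to(dirs)  # (M, 3, 3), R e_z = n_source
    table = np.empty((M, K, M))
    off = offsets.astype(float)
    for s in range(M):
        local_y = off @ R[s]            # R^T d  for all offsets
        local_n = dirs @ R[s]           # R^T n  for all targets
        table[s] = kernel_3d(
            local_y[:, None, :], local_n[None, :, :], params
        )
    return table


def build_kernel_lut(
    params: EnhancementParams,
    sampling: SphereSampling,
    half_width: int | None = None,
    mass_tolerance: float = 2e-2,
) -> KernelLUT:
    """Discretize the enhancement kernel into a normalized lookup table.

    The canonical e_z-aligned kernel is transported to every source
    orientation by the minimal rotation ``R_n`` (the kernel is axially
    symmetric, so the choice of ``R_n`` does not matter beyond the chart's
    degenerate tolerance).  Raises if the spatial window clips more than
    ``mass_tolerance`` of the kernel mass, naming a sufficient half-width.
    """
    if half_width is None:
        half_width = default_half_width(params, mass_tolerance)
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    if sampling.n_directions < 42:
        raise ValueError("kernel LUT needs a sampling with >= 42 directions")

    h = half_width
    rng = np.arange(-h, h + 1)
    offsets = np.stack(
        np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1
    ).reshape(-1, 3)

    # Tail-mass check on a doubled window for the canonical source e_z.
    w = sampling.weights
    big = np.arange(-2 * h, 2 * h + 1)
    boff = np.stack(np.meshgrid(big, big, big, indexing="ij"), axis=-1).reshape(-1, 3)
    kb = kernel_3d(
        boff[:, None, :].astype(float), sampling.directions[None, :, :], params
    )
    inside = np.all(np.abs(boff) <= h, axis=1)
    total = float(np.sum(kb * w))
    clipped = float(np.sum(kb[~inside] * w))
    if total > 0 and clipped / total >= mass_tolerance:
        from scipy.stats import norm

        sigma = 2.0 * np.sqrt(params.d33 * params.t)
        need = int(np.ceil(sigma * norm.isf(mass_tolerance / 2.0)))
        raise ValueError(
            f"window half_width={h} clips {clipped / total:.2%} of kernel mass "
            f"(tolerance {mass_tolerance:.0e}); use half_width >= {need}"
        )

    table = _raw_table(params, sampling, offsets)

    # Project onto the symmetries the exact semigroup kernel has:
    # adjoint exchange (s, d, t) -> (t, -d, s) and antipodal flips.
    flip = np.ascontiguousarray(offsets[::-1])  # -offsets under this ordering
    assert np.array_equal(flip, -offsets)
    exchanged = np.transpose(table[:, ::-1, :], (2, 1, 0))
    table = 0.5 * (table + exchanged)
    ai = sampling.antipodal_index
    table = 0.25 * (
        table
        + table[ai][:, ::-1, :]          # source flip (p(-y, n) = p(y, n) used)
        + table[:, :, ai]
        + table[ai][:, ::-1, :][:, :, ai]
    )
    # Re-symmetrize the exchange after the antipodal average.
    exchanged = np.transpose(table[:, ::-1, :], (2, 1, 0))
    table = 0.5 * (table + exchanged)

    # Symmetric Sinkhorn: diagonal scaling making every source slice's
    # quadrature mass exactly 1 (and by symmetry every target slice's too).
    # Iterated on the offset-summed (source x target) matrix, applied to the
    # full table once.
    A = table.sum(axis=1)  # (M, M), symmetric
    scale = np.ones(sampling.n_directions)
    for _ in range(500):
        mass = (A * scale[None, :]) @ w * scale
        if np.max(np.abs(mass - 1.0)) < 1e-15:
            break
        scale /= np.sqrt(mass)
    table *= scale[:, None, None] * scale[None, None, :]
    mass = np.einsum("skt,t->s", table, w)
    np.divide(table, mass[:, None, None], out=table)  # exact final row fix
    logger.info(
        "kernel LUT built: M=%d, half_width=%d, clipped tail %.2e, "
        "sinkhorn scale spread %.3f",
        sampling.n_directions, h, clipped / max(total, 1e-300),
        float(np.max(scale) / np.min(scale)),
    )
    return KernelLUT(
        params=params,
        sampling=sampling,
        half_width=h,
        offsets=offsets,
        table=table,
    )
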