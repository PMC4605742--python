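"""FOD estimation: constrained spherical deconvolution and a DTI baseline.

CSD recovers the fiber orientation distribution by deconvolving a
single-fiber response function (a zonal kernel) from the measured diffusion
signal, with an iteratively reweighted soft non-negativity constraint:
amplitudes of the current iterate that fall below a threshold
``tau * mean(FOD)`` are penalized quadratically with weight ``lambda^2``
until the constraint set stops changing.

The DTI-based FOD baseline maps a fitted diffusion tensor D to the sphere
function ``(n^T D^{-1} n)^{-3/2}`` (the orientation density of a Gaussian
diffusion profile), globally normalized over the analysis mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from se3fod.enhance import FODField, SHField
from se3fod.sphere import (
    SHBasis,
    SphereSampling,
    ZonalKernel,
    cached_icosphere,
    sh_basis_matrix,
    zonal_from_samples,
)

logger = logging.getLogger(__name__)


@dataclass
class DWSignal:
    """Diffusion-weighted attenuations relative to unit b=0 intensity.

    ``values`` has shape ``grid + (n_gradients,)`` (any number of leading
    spatial axes, or none for a single voxel).
    """

    gradients: np.ndarray  # (N_o, 3) unit vectors
    b_value: float
    values: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.gradients = np.asarray(self.gradients, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        norms = np.linalg.norm(self.gradients, axis=1)
        if not np.all(np.abs(norms - 1.0) < 1e-6):
            raise ValueError("gradient directions must be unit vectors")
        if self.values.shape[-1] != self.gradients.shape[0]:
            raise ValueError("last axis of values must match gradient count")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("signal values must be finite and nonnegative")

    @property
    def n_gradients(self) -> int:
        return self.gradients.shape[0]


@dataclass
class CSDConfig:
    """CSD hyperparameters.

    tau = 0.1, lambda = 1.0, i_max = 50 follow common practice in the CSD
    literature; the constraint sampling is a frequency-5 icosphere
    (252 directions).
    """

    l_max: int = 8
    lam: float = 1.0
    tau: float = 0.1
    i_max: int = 50
    constraint_frequency: int = 5
    coef_tol: float = 1e-6

    def __post_init__(self):
        if self.l_max % 2 != 0 or self.l_max < 0:
            raise ValueError("l_max must be even and nonnegative")
        if self.lam < 0 or self.tau <= 0 or self.i_max < 1:
            raise ValueError("invalid CSD configuration")

    @property
    def constraint_sampling(self) -> SphereSampling:
        return cached_icosphere(self.constraint_frequency)


@dataclass
class TensorField:
    """Per-voxel symmetric positive-definite diffusion tensors (mm^2/s)."""

    tensors: np.ndarray  # (..., 3, 3)
    clipped: np.ndarray = field(default=None)  # bool mask of eigenvalue clips

    def __post_init__(self):
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.shape[-2:] != (3, 3):
            raise ValueError("tensors must be (..., 3, 3)")
        if self.clipped is None:
            self.clipped = np.zeros(self.tensors.shape[:-2], dtype=bool)


def _effective_l_max(l_max: int, n_gradients: int) -> int:
    """Cap l_max so the coefficient count never exceeds the measurements.

    Super-resolution is deliberately disabled: 32 directions support at
    most l_max = 6 (28 coefficients), 64 support l_max = 8 (45).
    """
    lm = l_max
    while lm > 0 and (lm + 1) * (lm + 2) // 2 > n_gradients:
        lm -= 2
    return lm


def _csd_matrices(gradients, response: ZonalKernel, config: CSDConfig):
    basis = SHBasis(_effective_l_max(config.l_max, len(gradients)))
    fwd = sh_basis_matrix(basis, gradients) * response.convolution_factors(basis)
    constraint = sh_basis_matrix(basis, config.constraint_sampling)
    return basis, fwd, constraint


def csd_fit_voxel(
    signal: np.ndarray,
    response: ZonalKernel,
    config: CSDConfig | None = None,
    gradients: np.ndarray | None = None,
    _matrices=None,
):
    """Constrained spherical deconvolution of a single voxel's signal.

    Returns ``(coefficients, info)`` with ``info`` a dict holding the
    iteration count and a convergence flag.  The initial iterate is the
    data-driven (unconstrained, lightly damped) solution; each following
    iterate solves the data term plus ``lam^2`` times the squared
    amplitudes at the constraint directions where the previous iterate
    falls below ``tau`` times its mean.  Iteration stops when the
    constraint set is unchanged (with a small coefficient-delta guard) or
    at ``i_max``.
    """
    config = config or CSDConfig()
    if _matrices is None:
        if gradients is None:
            raise ValueError("either gradients or precomputed matrices required")
        _matrices = _csd_matrices(gradients, response, config)
    basis, fwd, constraint = _matrices
    signal = np.asarray(signal, dtype=float)

    # Data-driven initialisation (tiny Tikhonov damping for conditioning).
    AtA = fwd.T @ fwd
    damp = 1e-8 * np.trace(AtA) / AtA.shape[0]
    Atb = fwd.T @ signal
    try:
        coef = np.linalg.solve(AtA + damp * np.eye(AtA.shape[0]), Atb)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError(f"singular CSD normal equations: {exc}")
    if config.lam == 0:
        return coef, {"iterations": 0, "converged": True}

    lam2 = config.lam ** 2
    prev_set = None
    converged = False
    iterations = 0
    for iterations in range(1, config.i_max + 1):
        amp = constraint @ coef
        tau_h = config.tau * float(np.mean(amp))
        active = amp < tau_h
        if prev_set is not None and np.array_equal(active, prev_set):
            converged = True
            break
        L = constraint[active]
        M = AtA + lam2 * (L.T @ L)
        new_coef = np.linalg.solve(M + damp * np.eye(M.shape[0]), Atb)
        delta = float(np.max(np.abs(new_coef - coef)))
        coef = new_coef
        prev_set = active
        if delta < config.coef_tol:
            converged = True
            break
    return coef, {"iterations": iterations, "converged": converged}


def csd_fit_volume(
    dw: DWSignal,
    response: ZonalKernel,
    config: CSDConfig | None = None,
    mask: np.ndarray | None = None,
) -> SHField:
    """Voxelwise CSD over a volume; masked-out voxels get zero coefficients."""
    config = config or CSDConfig()
    matrices = _csd_matrices(dw.gradients, response, config)
    basis = matrices[0]
    grid = dw.values.shape[:-1]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    coef = np.zeros(grid + (basis.n_coefficients,))
    iters = []
    flat_vals = dw.values[mask]
    out = np.empty((flat_vals.shape[0], basis.n_coefficients))
    for i, sig in enumerate(flat_vals):
        out[i], info = csd_fit_voxel(sig, response, config, _matrices=matrices)
        iters.append(info["iterations"])
    coef[mask] = out
    if iters:
        logger.info(
            "CSD volume: %d voxels, iterations median %d max %d",
            len(iters), int(np.median(iters)), int(np.max(iters)),
        )
    return SHField(basis=basis, coefficients=coef, voxel_size=dw.voxel_size)


def estimate_response(
    dw: DWSignal, single_fiber_voxels, l_max: int = 8
) -> ZonalKernel:
    """Estimate the single-fiber response from selected coherent voxels.

    Each voxel's principal fiber direction is taken from a local tensor
    fit; its signal is expressed as a function of the angle between the
    gradient and that direction, signals are pooled, and a zonal SH kernel
    is fitted.
    """
    idx = list(single_fiber_voxels)
    if len(idx) == 0:
        raise ValueError("need at least one single-fiber voxel")
    vals = dw.values.reshape(-1, dw.n_gradients) if dw.values.ndim > 1 else dw.values[None]
    if dw.values.ndim > 1:
        flat_index = np.ravel_multi_index(np.array(idx).T, dw.values.shape[:-1])
        signals = vals[flat_index]
    else:
        signals = vals
    angles, pooled = [], []
    for sig in signals:
        D = _fit_tensor_single(sig, dw.gradients, dw.b_value)
        evals, evecs = np.linalg.eigh(D)
        principal = evecs[:, np.argmax(evals)]
        cosang = np.abs(dw.gradients @ principal)
        angles.append(np.arccos(np.clip(cosang, 0.0, 1.0)))
        pooled.append(sig)
    theta = np.concatenate(angles)
    values = np.concatenate(pooled)
    lm = _effective_l_max(l_max, dw.n_gradients)
    return zonal_from_samples(values, theta, lm)


def _fit_tensor_single(signal, gradients, b_value, eps=1e-10):
    """Log-linear least-squares single-voxel tensor fit."""
    g = gradients
    design = np.stack(
        [
            g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
        ],
        axis=1,
    )
    y = -np.log(np.maximum(signal, eps)) / b_value
    comp, *_ = np.linalg.lstsq(design, y, rcond=None)
    D = np.array(
        [
            [comp[0], comp[3], comp[4]],
            [comp[3], comp[1], comp[5]],
            [comp[4], comp[5], comp[2]],
        ]
    )
    return D


def dti_fit(dw: DWSignal, eigenvalue_floor: float = 1e-6) -> TensorField:
    """Voxelwise log-linear tensor fit; eigenvalues clipped to stay SPD.

    Requires at least 6 non-collinear gradients (b=0 intensity is the
    normalization convention, so only the 6 tensor components are fitted).
    """
    if dw.n_gradients < 6:
        raise ValueError("tensor fit requires >= 6 gradients")
    g = dw.gradients
    design = np.stack(
        [
            g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
        ],
        axis=1,
    )
    if np.linalg.matrix_rank(design) < 6:
        raise ValueError("gradient set is degenerate for a tensor fit")
    grid = dw.values.shape[:-1]
    y = -np.log(np.maximum(dw.values.reshape(-1, dw.n_gradients), 1e-10)) / dw.b_value
    comp, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    comp = comp.T  # (V, 6)
    V = comp.shape[0]
    D = np.empty((V, 3, 3))
    D[:, 0, 0], D[:, 1, 1], D[:, 2, 2] = comp[:, 0], comp[:, 1], comp[:, 2]
    D[:, 0, 1] = D[:, 1, 0] = comp[:, 3]
    D[:, 0, 2] = D[:, 2, 0] = comp[:, 4]
    D[:, 1, 2] = D[:, 2, 1] = comp[:, 5]
    evals, evecs = np.linalg.eigh(D)
    clipped = np.any(evals < eigenvalue_floor, axis=1)
    if np.any(clipped):
        logger.warning("tensor fit: %d voxels had eigenvalues clipped", clipped.sum())
    evals = np.maximum(evals, eigenvalue_floor)
    D = np.einsum("vij,vj,vkj->vik", evecs, evals, evecs)
    return TensorField(
        tensors=D.reshape(grid + (3, 3)), clipped=clipped.reshape(grid)
    )


def dti_fod(
    tensors: TensorField,
    sampling: SphereSampling,
    domain_mask: np.ndarray | None = None,
    voxel_volume: float = 1.0,
) -> FODField:
    """DTI-based FOD: U(y, n) ~ (n^T D(y)^{-1} n)^{-3/2}.

    Normalized by the single global constant
    ``1 / (4 pi * integral over the domain of sqrt(det D))`` so that the
    field integrates consistently across voxels; the domain is the analysis
    mask (all voxels if none given).
    """
    D = tensors.tensors
    grid = D.shape[:-2]
    if domain_mask is None:
        domain_mask = np.ones(grid, dtype=bool)
    dets = np.linalg.det(D[domain_mask])
    if np.any(dets <= 0):
        bad = np.argwhere(domain_mask)[dets <= 0][0]
        raise ValueError(f"singular tensor at voxel {tuple(int(i) for i in bad)}")
    norm_const = 1.0 / (4.0 * np.pi * float(np.sum(np.sqrt(dets)) * voxel_volume))
    Dinv = np.linalg.inv(D)
    n = sampling.directions
    quad = np.einsum("...ij,di,dj->...d", Dinv, n, n)
    vals = np.zeros(grid + (sampling.n_directions,))
    vals[domain_mask] = norm_const * quad[domain_mask] ** (-1.5)
    return FODField(sampling=sampling, values=vals)
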