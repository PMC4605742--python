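"""Sphere sampling, real symmetric spherical harmonics, and zonal convolution.

All orientation machinery in the package lives on a geodesic icosphere: the
icosahedron subdivided at frequency ``f`` and projected to the unit sphere,
giving ``10 f^2 + 2`` vertices that come in exact antipodal pairs.  FODs are
antipodally symmetric functions on S^2, so they are expanded in a *real,
orthonormal, even-order* spherical-harmonic basis with (l, m) ordered
lexicographically (l = 0, 2, ..., l_max; m = -l..l).  Coefficient volumes are
only interchangeable with other software together with this basis tag
(``"real-sym-lex"``).
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, SphericalVoronoi, cKDTree
from scipy.special import sph_harm_y

logger = logging.getLogger(__name__)

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0

# Icosahedron: 12 vertices in antipodal pairs, 20 faces.
_ICO_VERTS = np.array(
    [
        (-1, _GOLDEN, 0), (1, _GOLDEN, 0), (-1, -_GOLDEN, 0), (1, -_GOLDEN, 0),
        (0, -1, _GOLDEN), (0, 1, _GOLDEN), (0, -1, -_GOLDEN), (0, 1, -_GOLDEN),
        (_GOLDEN, 0, -1), (_GOLDEN, 0, 1), (-_GOLDEN, 0, -1), (-_GOLDEN, 0, 1),
    ],
    dtype=float,
)
_ICO_FACES = np.array(
    [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ],
    dtype=int,
)


@dataclass
class SphereSampling:
    """Antipodally organized unit directions on the sphere.

    Attributes
    ----------
    directions : (M, 3) float array
        Unit vectors; ``directions[antipodal_index[i]] == -directions[i]``
        exactly (the negation is enforced bitwise at construction).
    antipodal_index : (M,) int array
        Involution pairing each direction with its negation.
    frequency : int
        Geodesic subdivision frequency; ``M == 10 * frequency**2 + 2``.
    """

    directions: np.ndarray
    antipodal_index: np.ndarray
    frequency: int
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]

    @property
    def hemisphere_index(self) -> np.ndarray:
        """Indices of one representative per antipodal pair (z > 0 preferred)."""
        if "hemi" not in self._cache:
            idx = np.arange(self.n_directions)
            keep = idx < self.antipodal_index
            self._cache["hemi"] = idx[keep]
        return self._cache["hemi"]

    @property
    def faces(self) -> np.ndarray:
        """Triangular faces of the tessellation (from the convex hull)."""
        if "faces" not in self._cache:
            hull = ConvexHull(self.directions)
            self._cache["faces"] = hull.simplices
        return self._cache["faces"]

    @property
    def neighbors(self) -> list[np.ndarray]:
        """Per-vertex sorted arrays of mesh-adjacent vertex indices."""
        if "neighbors" not in self._cache:
            faces = self.faces
            edges = np.concatenate(
                [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]
            )
            edges = np.unique(np.sort(edges, axis=1), axis=0)
            adj: list[list[int]] = [[] for _ in range(self.n_directions)]
            for a, b in edges:
                adj[a].append(b)
                adj[b].append(a)
            self._cache["neighbors"] = [np.array(sorted(a)) for a in adj]
        return self._cache["neighbors"]

    @property
    def weights(self) -> np.ndarray:
        """Quadrature weights (spherical-Voronoi cell areas, summing to 4*pi).

        Falls back to uniform ``4*pi/M`` if the Voronoi construction fails.
        """
        if "weights" not in self._cache:
            try:
                sv = SphericalVoronoi(self.directions, radius=1.0)
                w = sv.calculate_areas()
            except Exception:  # pragma: no cover - degenerate samplings only
                logger.warning("SphericalVoronoi failed; using uniform weights")
                w = np.full(self.n_directions, 4.0 * np.pi / self.n_directions)
            self._cache["weights"] = w
        return self._cache["weights"]

    def validate(self) -> None:
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.all(np.abs(norms - 1.0) < 1e-12):
            raise ValueError("sampling directions must be unit vectors")
        ai = self.antipodal_index
        if not np.array_equal(ai[ai], np.arange(self.n_directions)):
            raise ValueError("antipodal_index must be an involution")
        if not np.allclose(
            self.directions[ai], -self.directions, atol=1e-12
        ):
            raise ValueError("antipodal_index must map to exact negations")


def make_icosphere(frequency: int) -> SphereSampling:
    """Geodesic icosphere of the given subdivision frequency.

    Each icosahedron edge is divided into ``frequency`` segments; the
    triangular lattice on every face is projected to the unit sphere.  The
    result has ``10 * frequency**2 + 2`` vertices in exact antipodal pairs.
    Frequency 61 gives 37212 vertices = 18606 antipodally distinct
    directions, the resolution used for FOD maxima detection.
    """
    frequency = int(frequency)
    if frequency < 1:
        raise ValueError("frequency must be >= 1")
    f = frequency
    base = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)

    # Barycentric lattice (i + j + k = f) on each face, before dedup.
    i, j = np.meshgrid(np.arange(f + 1), np.arange(f + 1), indexing="ij")
    keep = (i + j) <= f
    bi, bj = i[keep], j[keep]
    bk = f - bi - bj
    bary = np.stack([bi, bj, bk], axis=1) / float(f)

    pts = np.concatenate([bary @ base[face] for face in _ICO_FACES])
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)

    # Dedup shared edge/vertex points (identical up to fp noise).
    key = np.round(pts, 9)
    _, idx = np.unique(key, axis=0, return_index=True)
    pts = pts[np.sort(idx)]
    if pts.shape[0] != 10 * f * f + 2:
        raise RuntimeError(
            f"tessellation dedup produced {pts.shape[0]} vertices, "
            f"expected {10 * f * f + 2}"
        )

    # Antipodal pairing, then enforce exact negation bitwise.
    tree = cKDTree(pts)
    dist, anti = tree.query(-pts)
    if np.max(dist) > 1e-9 or np.any(anti == np.arange(len(pts))):
        raise RuntimeError("tessellation is not antipodally symmetric")
    rep = np.arange(len(pts)) < anti
    pts[anti[rep]] = -pts[rep]
    return SphereSampling(directions=pts, antipodal_index=anti, frequency=f)


# ---------------------------------------------------------------------------
# Spherical harmonics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SHBasis:
    """Real orthonormal even-order SH basis, (l, m) lexicographic."""

    l_max: int

    def __post_init__(self):
        if self.l_max < 0 or self.l_max % 2 != 0:
            raise ValueError("l_max must be an even nonnegative integer")

    @property
    def index_order(self) -> list[tuple[int, int]]:
        return [
            (l, m) for l in range(0, self.l_max + 1, 2) for m in range(-l, l + 1)
        ]

    @property
    def n_coefficients(self) -> int:
        return (self.l_max + 1) * (self.l_max + 2) // 2

    @property
    def orders(self) -> np.ndarray:
        """Order l of every coefficient."""
        return np.array([l for l, _ in self.index_order])


def _real_sh(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real orthonormal SH from scipy's complex Y_l^m (Condon-Shortley).

    m = 0: Y_l^0; m > 0: sqrt(2) (-1)^m Re Y_l^m; m < 0: sqrt(2) (-1)^m Im Y_l^|m|.
    """
    if m == 0:
        return sph_harm_y(l, 0, theta, phi).real
    y = sph_harm_y(l, abs(m), theta, phi)
    s = np.sqrt(2.0) * (-1.0) ** abs(m)
    return s * (y.real if m > 0 else y.imag)


def sh_basis_matrix(basis: SHBasis, sampling) -> np.ndarray:
    """Basis values, shape (n_directions, n_coefficients).

    ``sampling`` may be a :class:`SphereSampling` or a raw (M, 3) array of
    unit directions.
    """
    dirs = sampling.directions if isinstance(sampling, SphereSampling) else np.atleast_2d(sampling)
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])
    cols = [_real_sh(l, m, theta, phi) for l, m in basis.index_order]
    return np.stack(cols, axis=1)


def sh_fit(
    values: np.ndarray,
    basis: SHBasis,
    sampling,
    regularization: float = 0.0,
) -> np.ndarray:
    """Least-squares SH coefficients of sampled sphere values.

    ``values`` may be (M,) or (..., M); fitting is along the last axis.  An
    optional Laplace-Beltrami penalty ``regularization^2 * l^2 (l+1)^2``
    damps high orders.  Quadrature weights are used when ``sampling`` is a
    :class:`SphereSampling`, making the fit an (approximate) projection.
    """
    B = sh_basis_matrix(basis, sampling)
    m, c = B.shape
    if m < c:
        raise np.linalg.LinAlgError(
            f"{m} directions cannot determine {c} coefficients"
        )
    if isinstance(sampling, SphereSampling):
        w = sampling.weights
    else:
        w = np.full(m, 4.0 * np.pi / m)
    values = np.asarray(values, dtype=float)
    A = B.T * w  # (c, m)
    G = A @ B
    if regularization > 0:
        lb = basis.orders ** 2 * (basis.orders + 1) ** 2
        G = G + (regularization ** 2) * np.diag(lb.astype(float))
    rhs = values @ A.T  # (..., c)
    cond = np.linalg.cond(G)
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"ill-conditioned SH design (cond={cond:.2e}); "
            "add directions or reduce l_max"
        )
    return np.linalg.solve(G, rhs[..., None])[..., 0] if rhs.ndim > 1 else np.linalg.solve(G, rhs)


def sh_eval(coefficients: np.ndarray, basis: SHBasis, sampling) -> np.ndarray:
    """Evaluate SH coefficients on directions; linear, antipodally symmetric."""
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape[-1] != basis.n_coefficients:
        raise ValueError(
            f"expected {basis.n_coefficients} coefficients, "
            f"got {coefficients.shape[-1]}"
        )
    B = sh_basis_matrix(basis, sampling)
    return coefficients @ B.T


# ---------------------------------------------------------------------------
# Zonal kernels and spherical (de)convolution
# ---------------------------------------------------------------------------

@dataclass
class ZonalKernel:
    """Axially symmetric kernel on S^2: one SH coefficient per even order.

    ``coefficients[k]`` is the (l=2k, m=0) coefficient of the kernel aligned
    with the z-axis, in the same real orthonormal basis as :class:`SHBasis`.
    """

    l_max: int
    coefficients: np.ndarray

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.l_max % 2 != 0:
            raise ValueError("l_max must be even")
        if self.coefficients.shape != (self.l_max // 2 + 1,):
            raise ValueError("need one coefficient per even order 0..l_max")

    def convolution_factors(self, basis: SHBasis) -> np.ndarray:
        """Per-coefficient Funk-Hecke scaling for convolution with this kernel.

        Spherical convolution with a zonal kernel multiplies each (l, m)
        coefficient by ``sqrt(4 pi / (2l + 1)) * k_l``.
        """
        if basis.l_max > self.l_max:
            raise ValueError(
                f"kernel defined to l_max={self.l_max} < basis l_max={basis.l_max}"
            )
        ls = basis.orders
        kl = self.coefficients[ls // 2]
        return np.sqrt(4.0 * np.pi / (2 * ls + 1)) * kl


def zonal_convolve(
    coefficients: np.ndarray,
    zonal: ZonalKernel,
    basis: SHBasis,
    inverse: bool = False,
    floor: float = 1e-8,
) -> np.ndarray:
    """Spherical convolution (or deconvolution) with a zonal kernel.

    Forward mode realizes the single-fiber forward model ``K *_{S^2} g``;
    inverse mode divides per order and is the sharpening-deconvolution hook
    used after enhancement.  In inverse mode, convolution factors smaller in
    magnitude than ``floor`` are clipped to it (sign preserved) and a warning
    is logged.
    """
    factors = zonal.convolution_factors(basis)
    if inverse:
        small = np.abs(factors) < floor
        if np.any(small):
            logger.warning(
                "zonal deconvolution: %d order factors below floor %.1e clipped",
                int(np.sum(small)), floor,
            )
            factors = np.where(
                small, np.where(factors >= 0, floor, -floor), factors
            )
        factors = 1.0 / factors
    return np.asarray(coefficients, dtype=float) * factors


def zonal_from_samples(
    values: np.ndarray, polar_angles: np.ndarray, l_max: int
) -> ZonalKernel:
    """Fit a zonal kernel from samples of an axially symmetric function.

    ``values[i]`` is the function at polar angle ``polar_angles[i]`` from
    the z-axis (azimuth irrelevant by symmetry).
    """
    theta = np.asarray(polar_angles, dtype=float)
    ls = np.arange(0, l_max + 1, 2)
    cols = [_real_sh(l, 0, theta, np.zeros_like(theta)) for l in ls]
    B = np.stack(cols, axis=1)
    coef, *_ = np.linalg.lstsq(B, np.asarray(values, dtype=float), rcond=None)
    return ZonalKernel(l_max=l_max, coefficients=coef)


# ---------------------------------------------------------------------------
# The (beta, gamma) chart used by the enhancement kernel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AngularCoords:
    """Chart n(beta, gamma) = (sin b, -cos b sin g, cos b cos g)."""

    beta: float
    gamma: float
    degenerate: bool = False


def to_beta_gamma(n: np.ndarray) -> AngularCoords:
    """Invert the chart ``n(beta, gamma)`` for a unit vector.

    Vectorized over leading axes when ``n`` has shape (..., 3); then returns
    a tuple ``(beta, gamma, degenerate)`` of arrays instead of a dataclass.
    At n = +-e_x (cos beta = 0) gamma is undefined; it is returned as 0 with
    the degenerate flag set.
    """
    n = np.asarray(n, dtype=float)
    scalar = n.ndim == 1
    n = np.atleast_2d(n)
    if not np.all(np.abs(np.linalg.norm(n, axis=-1) - 1.0) < 1e-6):
        raise ValueError("directions must be unit vectors")
    ny, nz = n[..., 1], n[..., 2]
    c = np.hypot(ny, nz)  # |cos beta|
    degenerate = c < 1e-12
    # cos beta carries the sign of n_z so that gamma stays in (-pi/2, pi/2].
    sign = np.where(nz != 0, np.sign(nz), 1.0)
    cosbeta = sign * c
    gamma = np.where(
        degenerate, 0.0, np.arctan2(-ny * sign, np.abs(nz))
    )
    beta = np.arctan2(n[..., 0], cosbeta)
    if scalar:
        return AngularCoords(float(beta[0]), float(gamma[0]), bool(degenerate[0]))
    return beta, gamma, degenerate


def beta_gamma_to_n(beta, gamma) -> np.ndarray:
    """The chart itself: n = R_{e_x, gamma} R_{e_y, beta} e_z."""
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    return np.stack(
        [np.sin(beta), -np.cos(beta) * np.sin(gamma), np.cos(beta) * np.cos(gamma)],
        axis=-1,
    )


@functools.lru_cache(maxsize=8)
def cached_icosphere(frequency: int) -> SphereSampling:
    """Memoized :func:`make_icosphere` (tessellations are immutable)."""
    return make_icosphere(frequency)


def rotation_to(n: np.ndarray) -> np.ndarray:
    """Some rotation matrix R with R e_z = n (minimal geodesic rotation).

    For n in the southern pole's neighborhood the rotation axis degenerates;
    a fixed 180-degree rotation about e_x is used at n = -e_z.
    """
    n = np.asarray(n, dtype=float)
    single = n.ndim == 1
    n = np.atleast_2d(n)
    ez = np.array([0.0, 0.0, 1.0])
    v = np.cross(np.broadcast_to(ez, n.shape), n)
    c = n[..., 2]
    R = np.empty(n.shape[:-1] + (3, 3))
    s2 = np.einsum("...i,...i->...", v, v)
    ok = s2 > 1e-24
    # Rodrigues with the trigonometric simplification 1/(1+c).
    K = np.zeros_like(R)
    K[..., 0, 1], K[..., 0, 2] = -v[..., 2], v[..., 1]
    K[..., 1, 0], K[..., 1, 2] = v[..., 2], -v[..., 0]
    K[..., 2, 0], K[..., 2, 1] = -v[..., 1], v[..., 0]
    eye = np.broadcast_to(np.eye(3), R.shape)
    denom = np.where(ok, 1.0 + c, 1.0)
    R[:] = eye + K + (K @ K) / denom[..., None, None]
    flip = np.diag([1.0, -1.0, -1.0])  # n = -e_z
    R[~ok & (c < 0)] = flip
    R[~ok & (c > 0)] = np.eye(3)
    return R[0] if single else R
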