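"""Synthetic phantoms: bundle geometries, ground truth, DWI simulation.

The generator emulates the study conditions used throughout the package's
evaluation: single, crossing, and curved fiber bundles on a small voxel
grid; an axially symmetric single-fiber response; diffusion-weighted
signal formed by spherically convolving the response with the per-voxel
truth orientations; Rician noise with standard deviation 1/SNR of the unit
b=0 intensity; truth-fiber sampling and spurious-fiber injection for the
coherence tests.

Simulation uses the response-convolution forward model (the same model CSD
inverts) rather than a multi-compartment sub-voxel model; see the methods
note for what this does and does not exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from se3fod.bundles import FiberBundle, Streamline, compute_tangents
from se3fod.fod import DWSignal
from se3fod.sphere import ZonalKernel, zonal_from_samples

PEAK_MERGE_DEG = 5.0


@dataclass
class BundleGeometry:
    """A tube around a parametric centerline (mm units).

    kind: "straight" (start -> end), "arc" (circle section around ``center``
    in the plane spanned by u, v), or "spline" (cubic through waypoints).
    """

    kind: str
    radius: float
    weight: float = 1.0
    start: tuple | None = None
    end: tuple | None = None
    center: tuple | None = None
    arc_radius: float | None = None
    angle_span: tuple = (0.0, np.pi / 2)
    plane_u: tuple = (1.0, 0.0, 0.0)
    plane_v: tuple = (0.0, 1.0, 0.0)
    waypoints: np.ndarray | None = None

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("tube radius must be positive")
        if self.kind not in ("straight", "arc", "spline"):
            raise ValueError(f"unknown geometry kind {self.kind!r}")

    def arc_length(self) -> float:
        if self.kind == "straight":
            return float(np.linalg.norm(np.subtract(self.end, self.start)))
        if self.kind == "arc":
            return float(self.arc_radius * (self.angle_span[1] - self.angle_span[0]))
        pts, _ = self.sample(512)
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))

    def sample(self, n: int):
        """``n`` centerline points and unit tangents at uniform arclength."""
        if self.kind == "straight":
            a, b = np.asarray(self.start, float), np.asarray(self.end, float)
            ts = np.linspace(0.0, 1.0, n)
            pts = a + ts[:, None] * (b - a)
            tan = np.tile((b - a) / np.linalg.norm(b - a), (n, 1))
            return pts, tan
        if self.kind == "arc":
            c = np.asarray(self.center, float)
            u = np.asarray(self.plane_u, float)
            v = np.asarray(self.plane_v, float)
            u = u / np.linalg.norm(u)
            v = v - (v @ u) * u
            v = v / np.linalg.norm(v)
            phis = np.linspace(*self.angle_span, n)
            pts = c + self.arc_radius * (
                np.cos(phis)[:, None] * u + np.sin(phis)[:, None] * v
            )
            tan = -np.sin(phis)[:, None] * u + np.cos(phis)[:, None] * v
            return pts, tan
        from scipy.interpolate import CubicSpline

        wp = np.asarray(self.waypoints, float)
        chord = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(wp, axis=0), axis=1))]
        )
        cs = CubicSpline(chord, wp, axis=0)
        dense = np.linspace(0.0, chord[-1], 20 * n)
        seg = np.linalg.norm(np.diff(cs(dense), axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        targets = np.linspace(0.0, s[-1], n)
        ts = np.interp(targets, s, dense)
        pts = cs(ts)
        tan = cs(ts, 1)
        tan /= np.linalg.norm(tan, axis=1, keepdims=True)
        return pts, tan


@dataclass(frozen=True)
class NoiseModel:
    """Rician noise at an SNR relative to unit b=0 intensity (sigma = 1/SNR)."""

    snr: float = np.inf
    rng_seed: int = 0

    def __post_init__(self):
        if not self.snr > 0:
            raise ValueError("snr must be positive (np.inf for noiseless)")


@dataclass
class PhantomTruth:
    """Ground truth of a synthetic phantom.

    ``peaks`` maps voxel index tuples to (N_v, 3) arrays of unit truth
    directions; ``peak_weights`` holds the matching relative bundle
    weights.  Per bundle: dense centerline samples with tangents, tube
    voxel mask, and the two endpoint ROI masks used by the connection
    classifier.
    """

    grid_shape: tuple
    voxel_size: tuple
    geometries: list
    peaks: dict
    peak_weights: dict
    mask: np.ndarray
    bundle_masks: list
    roi_masks: list            # per bundle: (roiA, roiB) boolean volumes
    centerlines: list          # per bundle: (points, tangents)

    @property
    def n_bundles(self) -> int:
        return len(self.geometries)


def _merge_close_peaks(dirs: list, weights: list, tol_deg: float = PEAK_MERGE_DEG):
    merged_d, merged_w = [], []
    for d, w in zip(dirs, weights):
        for i, m in enumerate(merged_d):
            if np.abs(m @ d) > np.cos(np.radians(tol_deg)):
                if m @ d < 0:
                    d = -d
                total = merged_w[i] + w
                merged_d[i] = (merged_w[i] * m + w * d) / total
                merged_d[i] /= np.linalg.norm(merged_d[i])
                merged_w[i] = total
                break
        else:
            merged_d.append(np.asarray(d, float))
            merged_w.append(float(w))
    return merged_d, merged_w


def make_phantom(
    geometries: list, grid_shape: tuple, voxel_size: tuple = (1.0, 1.0, 1.0)
) -> PhantomTruth:
    """Rasterize tube bundles into per-voxel truth peaks and ROI masks.

    A voxel belongs to a bundle if its center lies within the tube radius
    of the centerline; its truth peak is the tangent at the nearest
    centerline point.  Peaks of different bundles closer than 5 degrees
    are merged (weight-averaged).  Endpoint ROIs are the tube
    cross-sections at the curve ends; overlapping endpoint ROIs of
    different bundles are an error.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    voxel_size = tuple(float(v) for v in voxel_size)
    idx = np.stack(
        np.meshgrid(*[np.arange(g) for g in grid_shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    centers = idx * np.asarray(voxel_size)

    per_voxel_dirs = {}
    per_voxel_wts = {}
    bundle_masks, roi_masks, centerlines = [], [], []
    for geo in geometries:
        n_dense = max(64, int(4 * geo.arc_length() / min(voxel_size)))
        pts, tans = geo.sample(n_dense)
        tree = cKDTree(pts)
        dist, nearest = tree.query(centers)
        inside = dist <= geo.radius
        bmask = inside.reshape(grid_shape)
        bundle_masks.append(bmask)
        centerlines.append((pts, tans))
        for flat_i in np.where(inside)[0]:
            key = tuple(idx[flat_i])
            per_voxel_dirs.setdefault(key, []).append(tans[nearest[flat_i]])
            per_voxel_wts.setdefault(key, []).append(geo.weight)
        rois = []
        for endpoint in (pts[0], pts[-1]):
            d_end = np.linalg.norm(centers - endpoint, axis=1)
            rois.append((d_end <= geo.radius).reshape(grid_shape))
        roi_masks.append(tuple(rois))

    for bi in range(len(geometries)):
        for bj in range(bi + 1, len(geometries)):
            for ra in roi_masks[bi]:
                for rb in roi_masks[bj]:
                    if np.any(ra & rb):
                        raise ValueError(
                            f"endpoint ROIs of bundles {bi} and {bj} overlap"
                        )

    peaks, weights = {}, {}
    mask = np.zeros(grid_shape, dtype=bool)
    for key, dirs in per_voxel_dirs.items():
        d, w = _merge_close_peaks(dirs, per_voxel_wts[key])
        peaks[key] = np.array(d)
        weights[key] = np.array(w) / np.sum(w)
        mask[key] = True
    return PhantomTruth(
        grid_shape=grid_shape,
        voxel_size=voxel_size,
        geometries=list(geometries),
        peaks=peaks,
        peak_weights=weights,
        mask=mask,
        bundle_masks=bundle_masks,
        roi_masks=roi_masks,
        centerlines=centerlines,
    )


def default_response(b_value: float = 3000.0, l_max: int = 8) -> ZonalKernel:
    """Single-fiber response: zonal fit of a prolate tensor signal.

    exp(-b n^T diag(1.7, 0.2, 0.2)e-3 n) at the configured b-value,
    i.e. typical white-matter diffusivities in mm^2/s.
    """
    theta = np.linspace(0.0, np.pi, 181)
    adc = 1.7e-3 * np.cos(theta) ** 2 + 0.2e-3 * np.sin(theta) ** 2
    return zonal_from_samples(np.exp(-b_value * adc), theta, l_max)


def zonal_eval_at_angles(response: ZonalKernel, cos_angles: np.ndarray) -> np.ndarray:
    """Evaluate a zonal kernel at given cosines of the polar angle."""
    from se3fod.sphere import _real_sh

    theta = np.arccos(np.clip(np.abs(cos_angles), 0.0, 1.0))
    out = np.zeros_like(theta, dtype=float)
    for k, l in enumerate(range(0, response.l_max + 1, 2)):
        out += response.coefficients[k] * _real_sh(
            l, 0, theta, np.zeros_like(theta)
        )
    return out


def simulate_dwi(
    truth: PhantomTruth,
    response: ZonalKernel,
    gradients: np.ndarray,
    b_value: float,
    noise: NoiseModel = NoiseModel(),
) -> DWSignal:
    """Simulate DW attenuations from the truth peaks.

    Noiseless signal per voxel = sum over truth peaks of
    weight * response(angle between gradient and peak); voxels outside the
    mask get the isotropic response mean (free-water-like background).
    Rician noise: S = sqrt((S0 + sigma X)^2 + (sigma Y)^2), sigma = 1/SNR.
    """
    gradients = np.asarray(gradients, dtype=float)
    grid = truth.grid_shape
    n_grad = gradients.shape[0]
    iso = float(
        np.mean(zonal_eval_at_angles(response, np.linspace(-1, 1, 65)))
    )
    signal = np.full(grid + (n_grad,), iso)
    for key, dirs in truth.peaks.items():
        w = truth.peak_weights[key]
        cosang = gradients @ dirs.T  # (n_grad, N_v)
        vals = zonal_eval_at_angles(response, cosang)
        signal[key] = vals @ w
    signal = np.clip(signal, 0.0, None)
    if np.isfinite(noise.snr):
        rng = np.random.default_rng(noise.rng_seed)
        sigma = 1.0 / noise.snr
        x = rng.standard_normal(signal.shape)
        y = rng.standard_normal(signal.shape)
        signal = np.sqrt((signal + sigma * x) ** 2 + (sigma * y) ** 2)
    return DWSignal(
        gradients=gradients,
        b_value=b_value,
        values=signal,
        voxel_size=truth.voxel_size,
    )


def uniform_gradients(n: int, rng_seed: int = 42) -> np.ndarray:
    """Approximately uniform gradient directions (electrostatic repulsion)."""
    rng = np.random.default_rng(rng_seed)
    pts = rng.standard_normal((n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    for _ in range(200):
        # antipodally symmetric Coulomb repulsion, projected to the sphere
        force = np.zeros_like(pts)
        for sgn in (1.0, -1.0):
            diff = pts[:, None, :] - sgn * pts[None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            np.fill_diagonal(d2, np.inf)
            if sgn < 0:
                d2[d2 < 1e-12] = np.inf
            force += (diff / d2[..., None] ** 1.5).sum(axis=1)
        pts += 0.001 * force
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def sample_truth_fibers(
    truth: PhantomTruth,
    n_fibers: int,
    step_mm: float,
    jitter_mm: float = 0.0,
    rng_seed: int = 0,
    bundle_index: int = 0,
) -> FiberBundle:
    """Sample fibers as offset copies of a bundle centerline.

    Each fiber is the centerline displaced by a random constant offset
    within the tube radius (perpendicular to the mean tangent), resampled
    at ``step_mm``, plus optional per-point Gaussian jitter.
    """
    geo = truth.geometries[bundle_index]
    length = geo.arc_length()
    if step_mm >= length:
        raise ValueError("step_mm must be smaller than the curve length")
    n_pts = int(np.floor(length / step_mm)) + 1
    pts, tans = geo.sample(n_pts)
    mean_tan = tans.mean(axis=0)
    mean_tan /= np.linalg.norm(mean_tan)
    rng = np.random.default_rng(rng_seed)
    fibers = []
    for i in range(n_fibers):
        if i == 0 and jitter_mm == 0.0:
            offset = np.zeros(3)
        else:
            v = rng.standard_normal(3)
            v -= (v @ mean_tan) * mean_tan
            norm = np.linalg.norm(v)
            v = v / norm if norm > 0 else np.zeros(3)
            offset = v * geo.radius * np.sqrt(rng.uniform())
        p = pts + offset
        if jitter_mm > 0:
            p = p + rng.normal(scale=jitter_mm, size=p.shape)
        fibers.append(Streamline(points=p, step=step_mm))
    return FiberBundle(fibers=fibers)


def inject_spurious(
    bundle: FiberBundle,
    k: int,
    lateral_offset_mm: float,
    angle_deg: float = 0.0,
    rng_seed: int = 0,
) -> FiberBundle:
    """Append k spurious fibers that depart laterally over their middle third.

    Each injected fiber copies a randomly chosen bundle fiber and adds a
    smooth displacement bump, peaking at ``lateral_offset_mm`` in a random
    perpendicular direction, supported on the middle third of the fiber.
    With ``angle_deg`` > 0 the departure slope is at least
    tan(angle_deg), giving a trapezoidal (kinked) profile.  The returned
    bundle records the injected indices in ``outlier_indices``.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng(rng_seed)
    fibers = list(bundle.fibers)
    tangents = list(bundle.tangents)
    outliers = list(bundle.outlier_indices)
    for _ in range(k):
        src = bundle.fibers[rng.integers(0, bundle.n_fibers)]
        pts = src.points.copy()
        n = pts.shape[0]
        i0, i1 = n // 3, 2 * n // 3
        mean_tan = (pts[-1] - pts[0])
        mean_tan /= max(np.linalg.norm(mean_tan), 1e-12)
        u = rng.standard_normal(3)
        u -= (u @ mean_tan) * mean_tan
        u /= max(np.linalg.norm(u), 1e-12)
        s = np.zeros(n)
        if i1 > i0:
            local = (np.arange(i0, i1) - i0) / max(i1 - 1 - i0, 1)
            if angle_deg > 0 and lateral_offset_mm > 0:
                slope = np.tan(np.radians(angle_deg))
                rise = np.minimum(local, 1.0 - local) * (i1 - i0) * src.step * slope
                s[i0:i1] = np.minimum(rise, lateral_offset_mm)
            else:
                s[i0:i1] = lateral_offset_mm * np.sin(np.pi * local) ** 2
        pts = pts + s[:, None] * u
        fl = Streamline(points=pts, step=src.step)
        outliers.append(len(fibers))
        fibers.append(fl)
        tangents.append(compute_tangents(fl))
    return FiberBundle(fibers=fibers, tangents=tangents, outlier_indices=outliers)
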