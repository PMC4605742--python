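"""Evaluation metrics: local angular error and global connection statistics.

The local metric compares FOD maxima against per-voxel ground-truth fiber
directions: for every truth peak, the angular distance to the nearest
estimated peak (antipodally identified), averaged over all truth peaks in
the mask.  Voxels where no peak is detected contribute the worst case of
90 degrees per truth peak (a documented convention penalizing dropouts).

The global metrics are a simplified connection classifier in the spirit of
tractography benchmarking suites: a streamline is a Valid Connection (VC)
if its endpoints lie in the two distinct endpoint ROIs of one bundle, an
Invalid Connection (IC) if they lie in ROIs that are not a truth pair, and
No Connection (NC) otherwise.  Derived quantities: CSR = 100 - NC,
VCCR = 100 VC / (VC + IC), and ABC = the percentage of bundle voxels
crossed by at least one of that bundle's valid streamlines, averaged over
bundles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from se3fod.bundles import FiberBundle
from se3fod.enhance import FODField, SHField
from se3fod.sphere import SphereSampling, cached_icosphere, sh_eval
from se3fod.synthetic import PhantomTruth
from se3fod.tracking import find_peaks

logger = logging.getLogger(__name__)


@dataclass
class ConnectionStats:
    VC: float = 0.0
    IC: float = 0.0
    NC: float = 0.0
    ABC: float = float("nan")
    CSR: float = float("nan")
    VCCR: float = float("nan")
    vc_assignment: list = None  # per-streamline bundle index or -1

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k) for k in ("VC", "IC", "NC", "ABC", "CSR", "VCCR")
        }


def peaks_by_voxel(
    field: SHField | FODField,
    sampling: SphereSampling | None = None,
    mask: np.ndarray | None = None,
    threshold: float = 0.1,
) -> dict:
    """Estimated peak directions per voxel (dict voxel -> (P, 3) array)."""
    if sampling is None:
        sampling = cached_icosphere(16)
    if isinstance(field, SHField):
        grid = field.grid_shape
        coef = field.coefficients
        vox = (
            np.argwhere(mask) if mask is not None
            else np.argwhere(np.ones(grid, dtype=bool))
        )
        amps = sh_eval(coef[tuple(vox.T)], field.basis, sampling)
    else:
        if field.sampling.n_directions != sampling.n_directions:
            sampling = field.sampling
        grid = field.grid_shape
        vox = (
            np.argwhere(mask) if mask is not None
            else np.argwhere(np.ones(grid, dtype=bool))
        )
        amps = field.values[tuple(vox.T)]
    out = {}
    for v, amp in zip(map(tuple, vox), amps):
        dirs, _ = find_peaks(amp, sampling, relative_threshold=threshold)
        out[v] = dirs
    return out


def angular_error(
    est,
    truth: PhantomTruth,
    sampling: SphereSampling | None = None,
    threshold: float = 0.1,
) -> float:
    """Average angular error (degrees) of estimated FOD peaks vs truth.

    ``est`` may be an SHField/FODField (peaks are detected on the dense
    tessellation) or a precomputed dict voxel -> (P, 3) peak directions.
    """
    if not truth.peaks:
        raise ValueError("phantom truth has an empty mask")
    if not isinstance(est, dict):
        est = peaks_by_voxel(est, sampling, mask=truth.mask, threshold=threshold)
    total, count = 0.0, 0
    for vox, true_dirs in truth.peaks.items():
        est_dirs = est.get(vox, np.empty((0, 3)))
        for td in true_dirs:
            count += 1
            if est_dirs.shape[0] == 0:
                total += 90.0
                continue
            cosang = np.abs(est_dirs @ td)
            total += np.degrees(np.arccos(np.clip(cosang.max(), -1.0, 1.0)))
    return total / count


def _point_to_voxel(points: np.ndarray, voxel_size, grid_shape) -> np.ndarray:
    """Nearest-node voxel ownership (half-open at the +0.5 boundary)."""
    idx = np.floor(points / np.asarray(voxel_size) + 0.5).astype(int)
    return np.clip(idx, 0, np.asarray(grid_shape) - 1)


def classify_connections(bundle: FiberBundle, truth: PhantomTruth) -> ConnectionStats:
    """VC/IC/NC percentages for a tractogram against the phantom truth."""
    n = bundle.n_fibers
    if n == 0:
        raise ValueError("empty tractogram")
    vc = ic = nc = 0
    assignment = []
    for fiber in bundle.fibers:
        if fiber.n_points == 0:
            nc += 1
            assignment.append(-1)
            logger.warning("zero-point streamline counted as NC")
            continue
        ends = _point_to_voxel(
            fiber.points[[0, -1]], truth.voxel_size, truth.grid_shape
        )
        hits = []  # (bundle index, roi side) per endpoint
        for e in ends:
            hit = None
            for bi, (ra, rb) in enumerate(truth.roi_masks):
                if ra[tuple(e)]:
                    hit = (bi, 0)
                    break
                if rb[tuple(e)]:
                    hit = (bi, 1)
                    break
            hits.append(hit)
        if hits[0] is None or hits[1] is None:
            nc += 1
            assignment.append(-1)
        elif hits[0][0] == hits[1][0] and hits[0][1] != hits[1][1]:
            vc += 1
            assignment.append(hits[0][0])
        else:
            ic += 1
            assignment.append(-1)
    return ConnectionStats(
        VC=100.0 * vc / n,
        IC=100.0 * ic / n,
        NC=100.0 * nc / n,
        vc_assignment=assignment,
    )


def global_metrics(
    stats: ConnectionStats, bundle: FiberBundle, truth: PhantomTruth
) -> ConnectionStats:
    """Complete the statistics with ABC, CSR and VCCR."""
    stats.CSR = 100.0 - stats.NC
    if stats.VC + stats.IC > 0:
        stats.VCCR = 100.0 * stats.VC / (stats.VC + stats.IC)
    else:
        stats.VCCR = float("nan")
        logger.warning("VCCR undefined: no connecting streamlines")
    coverages = []
    for bi, bmask in enumerate(truth.bundle_masks):
        covered = np.zeros(truth.grid_shape, dtype=bool)
        for fiber, assign in zip(bundle.fibers, stats.vc_assignment or []):
            if assign != bi:
                continue
            vox = _point_to_voxel(fiber.points, truth.voxel_size, truth.grid_shape)
            covered[tuple(vox.T)] = True
        denom = int(bmask.sum())
        if denom:
            coverages.append(100.0 * np.sum(covered & bmask) / denom)
    stats.ABC = float(np.mean(coverages)) if coverages else float("nan")
    return stats
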