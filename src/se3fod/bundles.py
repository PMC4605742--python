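"""Streamlines and fiber bundles.

A streamline is an ordered polyline sampled at (approximately) uniform
arclength steps; a bundle is a list of streamlines with per-point unit
tangents.  Antipodal doubling (each oriented point counted with both +-n)
is performed implicitly by the coherence computations, not by duplicating
storage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Streamline:
    """Ordered 3D points (mm, world coordinates) with a nominal step size."""

    points: np.ndarray  # (N, 3)
    step: float

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (N, 3)")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def length(self) -> float:
        return (self.n_points - 1) * self.step


def compute_tangents(streamline: Streamline) -> np.ndarray:
    """Unit tangents: central differences inside, one-sided at the ends."""
    pts = streamline.points
    if pts.shape[0] < 2:
        raise ValueError("streamline needs at least 2 points")
    diffs = np.diff(pts, axis=0)
    seg = np.linalg.norm(diffs, axis=1)
    dup = np.where(seg < 1e-12)[0]
    if dup.size:
        raise ValueError(f"duplicate consecutive points at index {dup[0]}")
    tan = np.empty_like(pts)
    tan[0] = diffs[0]
    tan[-1] = diffs[-1]
    if pts.shape[0] > 2:
        tan[1:-1] = pts[2:] - pts[:-2]
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    return tan


@dataclass
class FiberBundle:
    """Set of streamlines with per-point unit tangents.

    ``outlier_indices`` records fibers injected as known spurious ones by
    the synthetic module (empty for real tractograms).
    """

    fibers: list  # list[Streamline]
    tangents: list = field(default=None)  # list[(N_i, 3)]
    outlier_indices: list = field(default_factory=list)

    def __post_init__(self):
        if self.tangents is None:
            self.tangents = [compute_tangents(f) for f in self.fibers]
        for f, t in zip(self.fibers, self.tangents):
            if t.shape != f.points.shape:
                raise ValueError("tangents must be congruent with points")

    @property
    def n_fibers(self) -> int:
        return len(self.fibers)

    @property
    def n_total(self) -> int:
        """2 * total point count (forward and backward orientations)."""
        return 2 * sum(f.n_points for f in self.fibers)

    def subset(self, indices) -> "FiberBundle":
        indices = list(indices)
        out = [
            new_i
            for new_i, old_i in enumerate(indices)
            if old_i in self.outlier_indices
        ]
        return FiberBundle(
            fibers=[self.fibers[i] for i in indices],
            tangents=[self.tangents[i] for i in indices],
            outlier_indices=out,
        )

    def all_points(self) -> np.ndarray:
        return np.concatenate([f.points for f in self.fibers])

    def all_tangents(self) -> np.ndarray:
        return np.concatenate(self.tangents)

    def fiber_slices(self) -> list:
        """Per-fiber slices into the concatenated point arrays."""
        out, start = [], 0
        for f in self.fibers:
            out.append(slice(start, start + f.n_points))
            start += f.n_points
        return out
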