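"""File formats and conventions.

Conventions used everywhere: world coordinates are mm, RAS, related to
0-based voxel indices by ``world = index * spacing + origin`` (the NIfTI
affine); voxel ownership for masks is nearest-node with half-open rounding
at +0.5.  SH coefficient volumes are 4D NIfTI files accompanied by a JSON
sidecar recording the basis convention (``real-sym-lex``) and l_max;
reading a coefficient volume without its sidecar is an error.  Gradient
tables use the FSL dialect (3xN ``bvec``, 1xN ``bval`` text files).
Tractograms are TCK files (read and written through nibabel).
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import nibabel as nib

from se3fod.bundles import FiberBundle, Streamline
from se3fod.enhance import SHField
from se3fod.fod import DWSignal
from se3fod.sphere import SHBasis

SH_BASIS_TAG = "real-sym-lex"


def _sidecar_path(path) -> pathlib.Path:
    p = pathlib.Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def write_sh_field(field: SHField, path) -> None:
    img = nib.Nifti1Image(field.coefficients.astype(np.float64), field.affine)
    nib.save(img, str(path))
    sidecar = {"basis": SH_BASIS_TAG, "l_max": field.basis.l_max}
    _sidecar_path(path).write_text(json.dumps(sidecar))


def read_sh_field(path) -> SHField:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(
            f"SH volume {path} has no basis sidecar {sc}; coefficient volumes "
            f"are only interpretable with an explicit basis tag"
        )
    meta = json.loads(sc.read_text())
    if meta.get("basis") != SH_BASIS_TAG:
        raise ValueError(f"unsupported SH basis {meta.get('basis')!r}")
    img = nib.load(str(path))
    affine = img.affine
    voxel_size = tuple(np.abs(np.diag(affine)[:3]))
    return SHField(
        basis=SHBasis(int(meta["l_max"])),
        coefficients=np.asarray(img.dataobj, dtype=float),
        voxel_size=voxel_size,
        affine=affine,
    )


def read_gradient_table(bvec_path, bval_path):
    """FSL-style gradient table; non-unit bvecs are normalized with a warning."""
    bvec = np.loadtxt(bvec_path)
    bval = np.atleast_1d(np.loadtxt(bval_path))
    if bvec.shape[0] == 3 and bvec.shape != (3, 3):
        bvec = bvec.T
    norms = np.linalg.norm(bvec, axis=1)
    nonzero = norms > 0
    if not np.allclose(norms[nonzero], 1.0, atol=1e-6):
        import logging

        logging.getLogger(__name__).warning("non-unit bvec columns normalized")
    bvec[nonzero] /= norms[nonzero, None]
    return bvec, bval


def read_dwi(nifti_path, bvec_path, bval_path) -> DWSignal:
    """Load a DW volume; b=0 volumes are averaged out for normalization."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    voxel_size = tuple(np.abs(np.diag(img.affine)[:3]))
    bvec, bval = read_gradient_table(bvec_path, bval_path)
    is_b0 = bval < 50
    if np.any(is_b0):
        s0 = data[..., is_b0].mean(axis=-1)
        s0 = np.maximum(s0, 1e-10)
        data = data[..., ~is_b0] / s0[..., None]
        bvec, bval = bvec[~is_b0], bval[~is_b0]
    return DWSignal(
        gradients=bvec,
        b_value=float(np.median(bval)),
        values=np.clip(data, 0.0, None),
        voxel_size=voxel_size,
    )


def write_tracks(bundle: FiberBundle, path) -> None:
    from nibabel.streamlines import Tractogram, save as nib_save
    from nibabel.streamlines.tck import TckFile

    tractogram = Tractogram(
        [f.points.astype(np.float32) for f in bundle.fibers],
        affine_to_rasmm=np.eye(4),
    )
    step = bundle.fibers[0].step if bundle.n_fibers else 0.0
    tck = TckFile(tractogram, header={"step_size": str(step)})
    nib_save(tck, str(path))


def read_tracks(path) -> FiberBundle:
    tck = nib.streamlines.load(str(path))
    try:
        step = float(tck.header.get("step_size", 0.0))
    except (TypeError, ValueError):
        step = 0.0
    fibers = []
    for pts in tck.streamlines:
        pts = np.asarray(pts, dtype=float)
        if step <= 0 and pts.shape[0] > 1:
            step = float(np.median(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        fibers.append(Streamline(points=pts, step=step))
    return FiberBundle(fibers=fibers) if fibers else FiberBundle(fibers=[], tangents=[])


def write_scores(scores, path) -> None:
    with open(path, "w") as f:
        f.write("fiber,rfbc\n")
        for i, s in enumerate(np.asarray(scores)):
            f.write(f"{i},{s:.10g}\n")


def write_truth(truth, path) -> None:
    """Serialize phantom geometry (masks are regenerated on load)."""
    geos = []
    for g in truth.geometries:
        geos.append(
            {
                "kind": g.kind,
                "radius": g.radius,
                "weight": g.weight,
                "start": None if g.start is None else list(g.start),
                "end": None if g.end is None else list(g.end),
                "center": None if g.center is None else list(g.center),
                "arc_radius": g.arc_radius,
                "angle_span": list(g.angle_span),
                "plane_u": list(g.plane_u),
                "plane_v": list(g.plane_v),
                "waypoints": None
                if g.waypoints is None
                else np.asarray(g.waypoints).tolist(),
            }
        )
    doc = {
        "grid_shape": list(truth.grid_shape),
        "voxel_size": list(truth.voxel_size),
        "geometries": geos,
    }
    pathlib.Path(path).write_text(json.dumps(doc, indent=1))


def read_truth(path):
    from se3fod.synthetic import BundleGeometry, make_phantom

    doc = json.loads(pathlib.Path(path).read_text())
    geos = []
    for g in doc["geometries"]:
        kwargs = dict(g)
        if kwargs.get("waypoints") is not None:
            kwargs["waypoints"] = np.asarray(kwargs["waypoints"], dtype=float)
        if kwargs.get("angle_span") is not None:
            kwargs["angle_span"] = tuple(kwargs["angle_span"])
        geos.append(BundleGeometry(**kwargs))
    return make_phantom(geos, tuple(doc["grid_shape"]), tuple(doc["voxel_size"]))
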