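"""Standard-format I/O: NIfTI velocity volumes, STL/PLY surfaces, CSV, JSON.

Velocity dialects (the scanner's own format is proprietary, so two open ones
are defined):

* ``"velocity"`` — voxel values are m/s, one file per component, the cardiac
  phase as the 4th dimension;
* ``"phase"`` — voxel values are radians (pi * v / VENC), decoded with the
  VENC on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .core import FlowWaveform, MagnitudeSeries, VelocityField4D
from .geometry import Centerline
from .mesh import TriangleMesh

__all__ = [
    "write_velocity_nifti",
    "read_velocity_nifti",
    "write_magnitude_nifti",
    "read_magnitude_nifti",
    "write_stl",
    "read_stl",
    "write_ply",
    "read_ply",
    "write_centerline_csv",
    "read_centerline_csv",
    "write_waveform_csv",
    "read_waveform_csv",
    "write_json",
]

_COMPONENTS = ("vx", "vy", "vz")


def _affine(origin: np.ndarray, spacing: float) -> np.ndarray:
    a = np.eye(4)
    a[0, 0] = a[1, 1] = a[2, 2] = spacing
    a[:3, 3] = origin
    return a


def write_velocity_nifti(
    field: VelocityField4D, out_dir: Union[str, Path], prefix: str = "vel",
    dialect: str = "velocity",
) -> list:
    """One ``<prefix>_<comp>.nii.gz`` per component; phase is the 4th dim."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for c, name in enumerate(_COMPONENTS):
        data = np.moveaxis(field.velocity[..., c], 0, -1)  # (nx, ny, nz, T)
        if dialect == "phase":
            data = np.pi * data / field.venc
        elif dialect != "velocity":
            raise ValueError(f"unknown dialect {dialect!r}")
        img = nib.Nifti1Image(data.astype(np.float32), _affine(field.origin, field.spacing))
        img.header.set_xyzt_units("mm", "msec")
        p = out_dir / f"{prefix}_{name}.nii.gz"
        nib.save(img, p)
        paths.append(p)
    return paths


def read_velocity_nifti(
    paths: Sequence[Union[str, Path]],
    venc: float,
    dt_ms: float = 49.0,
    dialect: str = "velocity",
    lumen_mask: Optional[np.ndarray] = None,
) -> VelocityField4D:
    """Assemble a :class:`VelocityField4D` from three per-component volumes."""
    if venc is None or venc <= 0:
        raise ValueError("a positive VENC is required")
    if len(paths) != 3:
        raise ValueError("expected three component files (vx, vy, vz)")
    imgs = [nib.load(str(p)) for p in paths]
    shapes = {im.shape for im in imgs}
    if len(shapes) != 1:
        raise ValueError(f"mismatched component shapes: {sorted(shapes)}")
    affines = [im.affine for im in imgs]
    if not all(np.allclose(a, affines[0], atol=1e-6) for a in affines):
        raise ValueError("mismatched component affines")
    aff = affines[0]
    spacing = float(aff[0, 0])
    if not np.allclose(np.diag(aff)[:3], spacing, atol=1e-6):
        raise ValueError("only isotropic axis-aligned affines are supported")
    data = [np.asarray(im.dataobj, dtype=float) for im in imgs]
    if data[0].ndim == 3:
        data = [d[..., None] for d in data]
    vel = np.stack([np.moveaxis(d, -1, 0) for d in data], axis=-1)  # (T, nx, ny, nz, 3)
    if dialect == "phase":
        vel = venc * vel / np.pi
    elif dialect != "velocity":
        raise ValueError(f"unknown dialect {dialect!r}")
    return VelocityField4D(
        origin=aff[:3, 3].copy(), spacing=spacing, velocity=vel, venc=venc,
        dt_ms=dt_ms, lumen_mask=lumen_mask,
    )


def write_magnitude_nifti(
    series: MagnitudeSeries, path: Union[str, Path],
    origin: np.ndarray = (0.0, 0.0, 0.0), spacing: float = 0.5,
) -> Path:
    data = np.moveaxis(series.S, 0, -1)
    img = nib.Nifti1Image(data.astype(np.float32), _affine(np.asarray(origin, float), spacing))
    nib.save(img, str(path))
    return Path(path)


def read_magnitude_nifti(path: Union[str, Path], roi_vessel: np.ndarray) -> MagnitudeSeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    return MagnitudeSeries(S=np.moveaxis(data, -1, 0), roi_vessel=roi_vessel)


# ---------------------------------------------------------------------------
# Surfaces (ASCII STL / PLY)
# ---------------------------------------------------------------------------

def write_stl(mesh: TriangleMesh, path: Union[str, Path], name: str = "surface") -> Path:
    tri = mesh.triangles()
    normals = mesh.face_normals()
    with open(path, "w") as fh:
        fh.write(f"solid {name}\n")
        for f in range(mesh.n_faces):
            n = normals[f]
            fh.write(f"  facet normal {n[0]:.17g} {n[1]:.17g} {n[2]:.17g}\n")
            fh.write("    outer loop\n")
            for v in tri[f]:
                fh.write(f"      vertex {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write(f"endsolid {name}\n")
    return Path(path)


def read_stl(path: Union[str, Path]) -> TriangleMesh:
    verts, faces = [], []
    vmap: dict = {}
    with open(path) as fh:
        tri: list = []
        for line in fh:
            parts = line.split()
            if parts and parts[0] == "vertex":
                p = tuple(float(x) for x in parts[1:4])
                if p not in vmap:
                    vmap[p] = len(verts)
                    verts.append(p)
                tri.append(vmap[p])
                if len(tri) == 3:
                    faces.append(tri)
                    tri = []
    return TriangleMesh(np.array(verts), np.array(faces, dtype=np.int64))


def write_ply(mesh: TriangleMesh, path: Union[str, Path]) -> Path:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    return Path(path)


def read_ply(path: Union[str, Path]) -> TriangleMesh:
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError("not a PLY file")
        nv = nf = 0
        while True:
            line = fh.readline().strip()
            if line.startswith("element vertex"):
                nv = int(line.split()[-1])
            elif line.startswith("element face"):
                nf = int(line.split()[-1])
            elif line == "end_header":
                break
        verts = np.array([[float(x) for x in fh.readline().split()[:3]] for _ in range(nv)])
        faces = np.array(
            [[int(x) for x in fh.readline().split()[1:4]] for _ in range(nf)], dtype=np.int64
        )
    return TriangleMesh(verts, faces)


# ---------------------------------------------------------------------------
# CSV / JSON
# ---------------------------------------------------------------------------

def write_centerline_csv(cl: Centerline, path: Union[str, Path]) -> Path:
    df = pd.DataFrame(
        {
            "s": cl.arclength,
            "x_mm": cl.points[:, 0],
            "y_mm": cl.points[:, 1],
            "z_mm": cl.points[:, 2],
            "d_mm": cl.diameters,
        }
    )
    df.to_csv(path, index=False)
    return Path(path)


def read_centerline_csv(path: Union[str, Path]) -> Centerline:
    df = pd.read_csv(path)
    return Centerline(
        points=df[["x_mm", "y_mm", "z_mm"]].to_numpy(), diameters=df["d_mm"].to_numpy()
    )


def write_waveform_csv(wf: FlowWaveform, path: Union[str, Path]) -> Path:
    pd.DataFrame({"t_s": wf.times, "q_ml_s": wf.q}).to_csv(path, index=False)
    return Path(path)


def read_waveform_csv(path: Union[str, Path]) -> FlowWaveform:
    df = pd.read_csv(path)
    return FlowWaveform(times=df["t_s"].to_numpy(), q=df["q_ml_s"].to_numpy())


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.bool_):
            return bool(o)
        return super().default(o)


def write_json(obj: dict, path: Union[str, Path]) -> Path:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")
    return Path(path)
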