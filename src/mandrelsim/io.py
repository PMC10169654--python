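"""Readers and writers for the pipeline's on-disk formats.

Volumes are NIfTI (.nii/.nii.gz) with an axis-aligned affine; meshes
are STL or PLY; centerlines, catheter paths and shaping templates are
plain CSV; pick points are JSON.  All world coordinates are in mm, RAS
orientation, converted once at volume ingestion.
"""

from __future__ import annotations

import json
import os

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .catheter_sim import CatheterPath, PickedPoints
from .centerline import Centerline
from .segmentation import ImageVolume, SurfaceMesh
from .shaping import ShapingTemplate

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_volume",
    "write_volume",
    "read_picks",
    "write_picks",
    "read_centerline_csv",
    "write_centerline_csv",
    "read_path_csv",
    "write_path_csv",
    "read_template_csv",
    "write_template_csv",
    "write_vtk_polyline",
]

_MESH_EXT = {".stl", ".ply"}


def _check_mesh_ext(path: str) -> None:
    ext = os.path.splitext(str(path))[1].lower()
    if ext not in _MESH_EXT:
        raise ValueError(f"unsupported mesh format {ext!r} (use .stl or .ply)")


def read_mesh(path) -> SurfaceMesh:
    _check_mesh_ext(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        # process=True merges the duplicated vertices of STL triangle soup
        tm = trimesh.load_mesh(str(path), process=True)
    except Exception as exc:  # noqa: BLE001 - normalize loader errors
        raise ValueError(f"cannot parse mesh file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValueError(f"cannot parse mesh file {path}: no triangles found")
    return SurfaceMesh.from_trimesh(tm)


def write_mesh(mesh: SurfaceMesh, path) -> None:
    _check_mesh_ext(path)
    mesh.to_trimesh().export(str(path))


def has_outward_normals(mesh: SurfaceMesh) -> bool:
    """Signed-volume test: True when the winding encloses positive
    volume (outward normals)."""
    return mesh.enclosed_volume > 0


def read_volume(path) -> ImageVolume:
    img = nib.load(str(path))
    affine = img.affine
    lin = affine[:3, :3]
    gram = lin.T @ lin
    if not np.allclose(gram, np.diag(np.diag(gram)), atol=1e-6):
        raise ValueError("non-orthogonal affine is not supported")
    spacing = np.linalg.norm(lin, axis=0)
    return ImageVolume(np.asarray(img.dataobj), spacing, affine[:3, 3])


def write_volume(volume: ImageVolume, path) -> None:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    data = np.asarray(volume.data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_picks(path) -> dict:
    with open(path) as fh:
        raw = json.load(fh)
    out = {}
    for key in ("inlet", "dome", "tip", "first_contact"):
        if key in raw:
            out[key] = np.asarray(raw[key], dtype=float)
    if "proximal_s" in raw:
        out["proximal_s"] = float(raw["proximal_s"])
    return out


def write_picks(picks: dict, path) -> None:
    ser = {
        k: (list(np.asarray(v, dtype=float)) if np.ndim(v) else float(v))
        for k, v in picks.items()
    }
    with open(path, "w") as fh:
        json.dump(ser, fh, indent=2)


def catheter_picks(picks: dict) -> PickedPoints:
    return PickedPoints(
        proximal_s=picks["proximal_s"],
        tip=picks["tip"],
        first_contact=picks["first_contact"],
    )


def write_centerline_csv(cl: Centerline, path) -> None:
    pd.DataFrame(
        {
            "x": cl.points[:, 0],
            "y": cl.points[:, 1],
            "z": cl.points[:, 2],
            "arc_length": cl.arc_length,
            "local_radius": cl.local_radius,
        }
    ).to_csv(path, index=False)


def read_centerline_csv(path) -> Centerline:
    df = pd.read_csv(path)
    return Centerline(
        df[["x", "y", "z"]].to_numpy(),
        df["arc_length"].to_numpy(),
        df["local_radius"].to_numpy(),
    )


def write_path_csv(path_obj: CatheterPath, path) -> None:
    pd.DataFrame(
        {
            "x": path_obj.points[:, 0],
            "y": path_obj.points[:, 1],
            "z": path_obj.points[:, 2],
            "corrected": path_obj.corrected.astype(int),
        }
    ).to_csv(path, index=False)


def read_path_csv(path) -> CatheterPath:
    df = pd.read_csv(path)
    return CatheterPath(
        df[["x", "y", "z"]].to_numpy(), df["corrected"].to_numpy().astype(bool)
    )


def write_template_csv(template: ShapingTemplate, path) -> None:
    pd.DataFrame(
        template.rows, columns=["segment_length_mm", "bend_deg", "torsion_deg"]
    ).to_csv(path, index=False)


def read_template_csv(path) -> ShapingTemplate:
    df = pd.read_csv(path)
    return ShapingTemplate(
        df[["segment_length_mm", "bend_deg", "torsion_deg"]].to_numpy()
    )


def write_vtk_polyline(points: np.ndarray, path) -> None:
    """Legacy-ASCII VTK polydata with a single polyline, for viewers."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(points)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\npolyline\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {n} float\n")
        for p in points:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        fh.write(f"LINES 1 {n + 1}\n")
        fh.write(" ".join([str(n)] + [str(i) for i in range(n)]) + "\n")
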