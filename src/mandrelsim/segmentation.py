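"""Vessel lumen segmentation and surface reconstruction.

Turns a 3D angiographic volume into a watertight triangle mesh of the
lumen boundary: intensity thresholding to initialize, a region-based
(Chan--Vese-type) level-set refinement, marching-cubes surface
extraction, and an optional spherical region-of-interest crop.

World-coordinate convention used throughout the package: voxel (i, j, k)
sits at ``origin + index * spacing`` (voxel centers, 0-based indices),
all lengths in millimeters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy import ndimage
from skimage.measure import marching_cubes
from skimage.segmentation import morphological_chan_vese

__all__ = [
    "ImageVolume",
    "SurfaceMesh",
    "RoiSphere",
    "EmptySegmentationError",
    "threshold_segment",
    "levelset_refine",
    "extract_surface",
    "crop_roi",
]


class EmptySegmentationError(ValueError):
    """Raised when a segmentation step produces no foreground."""


@dataclass
class ImageVolume:
    """A 3D scalar grid with isotropic or anisotropic voxel spacing.

    Attributes
    ----------
    data : ndarray, shape (ni, nj, nk)
        Scalar intensities (or a binary mask).
    spacing : ndarray, shape (3,)
        Per-axis voxel spacing in mm; strictly positive.
    origin : ndarray, shape (3,)
        World position (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-dimensional")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three positive lengths")

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices for world points."""
        return (np.asarray(pts, dtype=float) - self.origin) / self.spacing


@dataclass
class SurfaceMesh:
    """Triangle mesh of the lumen boundary in world mm.

    Faces are wound counter-clockwise when viewed from outside
    (outward normals).  Containment queries require a watertight mesh;
    ``open_boundary`` flags meshes that were cropped open.
    """

    vertices: np.ndarray
    faces: np.ndarray
    open_boundary: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, **kw) -> "SurfaceMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), **kw)

    @property
    def is_watertight(self) -> bool:
        return not self.open_boundary and self.to_trimesh().is_watertight

    @property
    def area(self) -> float:
        return float(self.to_trimesh().area)

    @property
    def enclosed_volume(self) -> float:
        """Signed volume via the divergence theorem (positive = outward)."""
        return float(self.to_trimesh().volume)


@dataclass
class RoiSphere:
    """Spherical region of interest used to crop the reconstruction."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if not self.radius > 0:
            raise ValueError("ROI radius must be positive")


def threshold_segment(volume: ImageVolume, threshold: float) -> np.ndarray:
    """Binary mask ``data >= threshold`` restricted to the largest
    26-connected component.

    Raises
    ------
    EmptySegmentationError
        If no voxel reaches the threshold.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    raw = np.asarray(volume.data) >= threshold
    if not raw.any():
        raise EmptySegmentationError("empty segmentation: no voxel >= threshold")
    labels, n = ndimage.label(raw, structure=np.ones((3, 3, 3), dtype=int))
    if n == 1:
        return raw
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def levelset_refine(
    volume: ImageVolume,
    init_mask: np.ndarray,
    iterations: int = 50,
    smoothing: int = 1,
) -> np.ndarray:
    """Refine an initial mask by two-phase region-based level-set evolution.

    The energy separates the mean intensity inside and outside the front
    while a curvature term regularizes the interface (morphological
    Chan--Vese scheme).  ``iterations = 0`` returns the initial mask
    unchanged.
    """
    init_mask = np.asarray(init_mask).astype(bool)
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if not init_mask.any():
        raise EmptySegmentationError("level-set initialization is empty")
    if iterations == 0:
        return init_mask.copy()
    # the morphological scheme alternates two curvature operators through
    # a module-global cycle whose phase persists across calls; reset it so
    # repeated runs with identical inputs give identical masks
    from skimage.segmentation import morphsnakes as _msn

    _msn._curvop = _msn._fcycle(
        [
            lambda u: _msn.sup_inf(_msn.inf_sup(u)),
            lambda u: _msn.inf_sup(_msn.sup_inf(u)),
        ]
    )
    out = morphological_chan_vese(
        np.asarray(volume.data, dtype=float),
        num_iter=int(iterations),
        init_level_set=init_mask.astype(np.int8),
        smoothing=int(smoothing),
    )
    return out.astype(bool)


def extract_surface(
    mask: np.ndarray,
    spacing: np.ndarray,
    origin: np.ndarray = (0.0, 0.0, 0.0),
    smooth_sigma: float = 0.6,
) -> SurfaceMesh:
    """Marching-cubes isosurface of a binary mask at the 0.5 level.

    The mask is zero-padded by one voxel so the isosurface closes even
    when the foreground touches the grid boundary, and lightly Gaussian
    smoothed (``smooth_sigma`` in voxels) before contouring: the raw
    staircase isosurface overestimates area by ~10% while the smoothed
    one is within a few percent without moving the surface more than
    half a voxel.  Result is watertight with outward normals, world mm.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise EmptySegmentationError("cannot extract a surface from an empty mask")
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    padded = np.pad(mask, 1).astype(np.float32)
    if smooth_sigma > 0:
        padded = ndimage.gaussian_filter(padded, smooth_sigma)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    verts = verts + (origin - spacing)  # undo the one-voxel pad shift
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    tm.fix_normals()
    if tm.volume < 0:
        tm.invert()
    return SurfaceMesh.from_trimesh(tm)


def crop_roi(mesh: SurfaceMesh, roi: RoiSphere) -> SurfaceMesh:
    """Keep the faces whose centroids lie inside the ROI sphere.

    The crop is for visualization and bookkeeping only: boundary rings
    opened by the crop are left open and the output is flagged
    ``open_boundary``; containment queries must keep using the full
    watertight mesh.
    """
    if not mesh.is_watertight:
        raise ValueError("crop_roi expects a watertight input mesh")
    centroids = mesh.vertices[mesh.faces].mean(axis=1)
    keep = np.linalg.norm(centroids - roi.center, axis=1) <= roi.radius
    if not keep.any():
        raise ValueError("no face retained by the ROI crop")
    if keep.all():
        return replace(mesh)
    faces = mesh.faces[keep]
    used = np.unique(faces)
    remap = np.full(len(mesh.vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(mesh.vertices[used], remap[faces], open_boundary=True)
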