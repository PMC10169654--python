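"""Synthetic vessel + aneurysm phantoms with closed-form ground truth.

Every downstream stage (segmentation, centerline, catheter growth,
shaping) is exercised on parametric geometries whose interior, surface
and centerline are known analytically:

``straight_tube``
    A flat-capped cylinder of radius ``tube_radius`` along +z from 0 to
    ``tube_length``.
``bent_tube``
    A torus arc of tube radius ``tube_radius`` around a circle of
    radius ``arc_radius`` in the x-y plane, from azimuth 0 to
    ``arc_angle`` degrees, with flat angular end caps.
``sidewall_aneurysm``
    The straight tube with a spherical sac of radius
    ``aneurysm_radius`` attached to the wall at axial position
    ``aneurysm_offset`` (sac center on the +x side).
``bifurcation_aneurysm``
    A parent tube splitting into two symmetric branches in the x-z
    plane, with the sac seated on the flow divider beyond the apex.

The volume carries foreground intensity 100 on background 0 plus
seeded additive Gaussian noise.  The mesh is the zero level set of the
signed interior depth sampled on a fine grid (marching cubes), which
makes it watertight and sub-voxel accurate; ``analytic_contains`` /
``interior_depth`` are the exact oracles against which mesh-based
containment is validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.measure import marching_cubes
import trimesh

from .centerline import Centerline
from .segmentation import ImageVolume, SurfaceMesh

__all__ = [
    "PhantomSpec",
    "Phantom",
    "make_tube_phantom",
    "make_aneurysm_phantom",
    "make_phantom",
    "analytic_contains",
    "interior_depth",
    "suggest_picks",
]

KINDS = ("straight_tube", "bent_tube", "sidewall_aneurysm", "bifurcation_aneurysm")

FOREGROUND_INTENSITY = 100.0


@dataclass
class PhantomSpec:
    """Parameters of a synthetic vessel geometry (all lengths in mm).

    ``sac_center_offset`` is the radial distance of the sac center from
    the tube axis; by default it is ``tube_radius + aneurysm_radius/2``
    so the sac bulges through the wall with a wide ostium.
    """

    kind: str = "sidewall_aneurysm"
    tube_radius: float = 2.0
    tube_length: float = 40.0
    arc_radius: float = 10.0
    arc_angle: float = 90.0
    aneurysm_radius: float = 3.0
    aneurysm_offset: float = 25.0
    sac_center_offset: Optional[float] = None
    branch_angle: float = 40.0
    branch_length: float = 15.0
    voxel_spacing: float = 0.4
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if not self.tube_radius > 0:
            raise ValueError("tube_radius must be positive")
        if not self.voxel_spacing > 0:
            raise ValueError("voxel_spacing must be positive")
        if self.kind == "straight_tube" and not self.tube_length > 0:
            raise ValueError("tube_length must be positive")
        if self.kind == "bent_tube":
            if not self.arc_radius > 0 or not 0 < self.arc_angle <= 180:
                raise ValueError("need arc_radius > 0 and 0 < arc_angle <= 180")
            if self.arc_radius <= self.tube_radius:
                raise ValueError("arc_radius must exceed tube_radius")
        if self.kind in ("sidewall_aneurysm", "bifurcation_aneurysm"):
            if not self.aneurysm_radius > 0:
                raise ValueError("aneurysm_radius must be positive")
        if self.kind == "sidewall_aneurysm":
            if not 0 < self.aneurysm_offset < self.tube_length:
                raise ValueError("aneurysm_offset must fall along the tube")
            d = self.sac_radial_offset
            # ostium: the sphere must actually intersect the tube wall
            if d + self.aneurysm_radius <= self.tube_radius:
                raise ValueError("no ostium: sac entirely inside the tube")
            if d - self.aneurysm_radius >= self.tube_radius:
                raise ValueError("no ostium: sac entirely outside the tube")

    @property
    def sac_radial_offset(self) -> float:
        if self.sac_center_offset is not None:
            return self.sac_center_offset
        return self.tube_radius + 0.5 * self.aneurysm_radius

    @property
    def sac_center(self) -> np.ndarray:
        if self.kind == "sidewall_aneurysm":
            return np.array([self.sac_radial_offset, 0.0, self.aneurysm_offset])
        if self.kind == "bifurcation_aneurysm":
            apex = self.tube_length / 2.0
            return np.array(
                [0.0, 0.0, apex + self.tube_radius + 0.5 * self.aneurysm_radius]
            )
        raise ValueError("this phantom kind has no aneurysm sac")


@dataclass
class Phantom:
    """A generated geometry with its ground truth."""

    volume: ImageVolume
    mask: ImageVolume
    mesh: SurfaceMesh
    truth_centerline: Centerline
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# signed interior depth (positive inside), exact per primitive; the union
# depth is the max over primitives

def _depth_capped_cylinder(pts, radius, length):
    rho = np.hypot(pts[:, 0], pts[:, 1])
    return np.minimum.reduce([radius - rho, pts[:, 2], length - pts[:, 2]])


def _depth_arc_tube(pts, arc_radius, arc_angle_rad, tube_radius):
    rho = np.hypot(pts[:, 0], pts[:, 1])
    tube = tube_radius - np.hypot(rho - arc_radius, pts[:, 2])
    cap0 = pts[:, 1]  # signed distance to the azimuth-0 cap plane
    s, c = np.sin(arc_angle_rad), np.cos(arc_angle_rad)
    cap1 = pts[:, 0] * s - pts[:, 1] * c
    return np.minimum.reduce([tube, cap0, cap1])


def _depth_sphere(pts, center, radius):
    return radius - np.linalg.norm(pts - center, axis=1)


def _depth_capsule(pts, a, b, radius):
    ab = b - a
    t = np.clip((pts - a) @ ab / (ab @ ab), 0.0, 1.0)
    closest = a + t[:, None] * ab
    return radius - np.linalg.norm(pts - closest, axis=1)


def _bifurcation_geometry(spec: PhantomSpec):
    apex = np.array([0.0, 0.0, spec.tube_length / 2.0])
    ang = np.radians(spec.branch_angle)
    d = np.array([np.sin(ang), 0.0, np.cos(ang)])
    left = apex + spec.branch_length * d * np.array([1.0, 1.0, 1.0])
    right = apex + spec.branch_length * d * np.array([-1.0, 1.0, 1.0])
    return apex, left, right


def interior_depth(spec: PhantomSpec, points) -> np.ndarray:
    """Signed depth inside the phantom (mm, positive strictly inside)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if spec.kind == "straight_tube":
        return _depth_capped_cylinder(pts, spec.tube_radius, spec.tube_length)
    if spec.kind == "bent_tube":
        return _depth_arc_tube(
            pts, spec.arc_radius, np.radians(spec.arc_angle), spec.tube_radius
        )
    if spec.kind == "sidewall_aneurysm":
        return np.maximum(
            _depth_capped_cylinder(pts, spec.tube_radius, spec.tube_length),
            _depth_sphere(pts, spec.sac_center, spec.aneurysm_radius),
        )
    apex, left, right = _bifurcation_geometry(spec)
    return np.maximum.reduce(
        [
            _depth_capped_cylinder(pts, spec.tube_radius, apex[2]),
            _depth_capsule(pts, apex, left, spec.tube_radius),
            _depth_capsule(pts, apex, right, spec.tube_radius),
            _depth_sphere(pts, spec.sac_center, spec.aneurysm_radius),
        ]
    )


def analytic_contains(spec: PhantomSpec, point) -> bool:
    """Exact closed-form interior test for a single world point."""
    point = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(point)):
        raise ValueError("point must be finite")
    return bool(interior_depth(spec, point.reshape(1, 3))[0] > 0.0)


# ---------------------------------------------------------------------------
# grid construction

def _bounds(spec: PhantomSpec, margin: float):
    r = spec.tube_radius
    if spec.kind == "straight_tube":
        lo = np.array([-r, -r, 0.0])
        hi = np.array([r, r, spec.tube_length])
    elif spec.kind == "bent_tube":
        R = spec.arc_radius
        ang = np.radians(spec.arc_angle)
        xs = [np.cos(a) * R for a in np.linspace(0, ang, 64)]
        ys = [np.sin(a) * R for a in np.linspace(0, ang, 64)]
        lo = np.array([min(xs) - r, min(ys) - r, -r])
        hi = np.array([max(xs) + r, max(ys) + r, r])
    elif spec.kind == "sidewall_aneurysm":
        c = spec.sac_center
        ra = spec.aneurysm_radius
        lo = np.minimum([-r, -r, 0.0], c - ra)
        hi = np.maximum([r, r, spec.tube_length], c + ra)
    else:
        apex, left, right = _bifurcation_geometry(spec)
        c = spec.sac_center
        ra = spec.aneurysm_radius
        lo = np.minimum.reduce([[-r, -r, 0.0], left - r, right - r, c - ra])
        hi = np.maximum.reduce(
            [[r, r, apex[2]], left + r, right + r, c + ra]
        )
    return lo - margin, hi + margin


def _grid(spec: PhantomSpec, h: float):
    """Voxel-center grid covering the geometry.

    Centers are staggered half a voxel off the integer planes so that
    flat end caps (which sit on those planes) are straddled rather than
    sampled exactly; sampling a cap plane exactly would erode the mask
    by a full voxel there.
    """
    lo, hi = _bounds(spec, margin=2.0 * h)
    origin = (np.floor(lo / h) - 0.5) * h
    n = np.ceil((hi - origin) / h).astype(int) + 1
    return origin, n


def _depth_field(spec: PhantomSpec, origin, n, h):
    ii, jj, kk = np.meshgrid(
        np.arange(n[0]), np.arange(n[1]), np.arange(n[2]), indexing="ij"
    )
    pts = origin + np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]) * h
    return interior_depth(spec, pts).reshape(tuple(n))


def _make_mesh(spec: PhantomSpec) -> SurfaceMesh:
    h = min(spec.voxel_spacing, spec.tube_radius / 4.0)
    origin, n = _grid(spec, h)
    # extra sub-voxel shift so no sample sits exactly on the analytic
    # surface (exact zeros make the isosurface degenerate)
    origin = origin - 0.2371 * h
    n = n + 1
    depth = _depth_field(spec, origin, n, h)
    verts, faces, _, _ = marching_cubes(depth, level=0.0, spacing=(h, h, h))
    verts = verts + origin
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    tm.fix_normals()
    if tm.volume < 0:
        tm.invert()
    if not tm.is_watertight:
        raise RuntimeError("phantom mesh is unexpectedly not watertight")
    return SurfaceMesh.from_trimesh(tm)


def _truth_polyline(spec: PhantomSpec, step: float = 0.25) -> np.ndarray:
    # open tube ends lie exactly on the cap planes; inset them by 1 um so
    # every truth point is strictly interior (arc length is unaffected)
    eps = 1e-3
    if spec.kind == "straight_tube":
        z = np.arange(eps, spec.tube_length + step / 2, step)
        z[-1] = spec.tube_length - eps
        return np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    if spec.kind == "bent_tube":
        ang = np.radians(spec.arc_angle)
        n = max(int(np.ceil(spec.arc_radius * ang / step)), 2)
        d_ang = eps / spec.arc_radius
        phi = np.linspace(d_ang, ang - d_ang, n + 1)
        return np.column_stack(
            [
                spec.arc_radius * np.cos(phi),
                spec.arc_radius * np.sin(phi),
                np.zeros_like(phi),
            ]
        )
    if spec.kind == "sidewall_aneurysm":
        knots = [
            np.array([0.0, 0.0, eps]),
            np.array([0.0, 0.0, spec.aneurysm_offset]),
            spec.sac_center,
        ]
    else:
        apex, _, _ = _bifurcation_geometry(spec)
        knots = [np.array([0.0, 0.0, eps]), apex, spec.sac_center]
    pieces = []
    for a, b in zip(knots[:-1], knots[1:]):
        L = np.linalg.norm(b - a)
        n = max(int(np.ceil(L / step)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[:-1]
        pieces.append(a + t[:, None] * (b - a))
    pieces.append(knots[-1][None, :])
    return np.vstack(pieces)


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build volume + ground-truth mask + mesh + truth centerline."""
    h = spec.voxel_spacing
    origin, n = _grid(spec, h)
    depth = _depth_field(spec, origin, n, h)
    mask = depth > 0.0
    rng = np.random.default_rng(spec.seed)
    data = np.where(mask, FOREGROUND_INTENSITY, 0.0)
    if spec.noise_sigma > 0:
        data = data + rng.normal(0.0, spec.noise_sigma, size=mask.shape)
    spacing = np.full(3, h)
    volume = ImageVolume(data.astype(np.float32), spacing, origin)
    mask_vol = ImageVolume(mask, spacing, origin)
    mesh = _make_mesh(spec)
    pts = _truth_polyline(spec)
    radius = interior_depth(spec, pts)
    truth = Centerline.from_points(pts, local_radius=radius)
    return Phantom(volume, mask_vol, mesh, truth, spec)


def make_tube_phantom(spec: PhantomSpec) -> Phantom:
    """Straight or bent tube (no aneurysm)."""
    if spec.kind not in ("straight_tube", "bent_tube"):
        raise ValueError("make_tube_phantom expects a tube kind")
    return make_phantom(spec)


def make_aneurysm_phantom(spec: PhantomSpec) -> Phantom:
    """Tube or Y-junction carrying a saccular aneurysm."""
    if spec.kind not in ("sidewall_aneurysm", "bifurcation_aneurysm"):
        raise ValueError("make_aneurysm_phantom expects an aneurysm kind")
    return make_phantom(spec)


def suggest_picks(phantom: Phantom, variant: int = 0) -> dict:
    """Plausible pick points for a phantom, as a plain dict with keys
    ``proximal_s``, ``tip``, ``first_contact``.

    ``variant`` perturbs the wall-contact azimuth and axial offset
    deterministically, giving a family of realistic pick sets for
    property testing.  The tip is the sac centroid (aneurysm phantoms)
    or a point near the distal end of the axis (tubes); the first
    contact sits just inside the wall, proximal of the tip, so the
    initial growth direction has a proximal component.
    """
    spec = phantom.spec
    rng = np.random.default_rng(1000 + variant)
    r = spec.tube_radius
    inset = 0.85 * r  # radial position of the wall-contact point
    if spec.kind == "straight_tube":
        tip = np.array([0.0, 0.0, spec.tube_length - 1.5 * r])
        psi = rng.uniform(0, 2 * np.pi)
        dz = rng.uniform(2.0 * r, 3.5 * r)
        fc = np.array([inset * np.cos(psi), inset * np.sin(psi), tip[2] - dz])
    elif spec.kind == "bent_tube":
        ang = np.radians(spec.arc_angle)
        phi_tip = ang * 0.95
        tip = spec.arc_radius * np.array(
            [np.cos(phi_tip), np.sin(phi_tip), 0.0]
        )
        phi_c = ang * rng.uniform(0.45, 0.7)
        rad = spec.arc_radius + inset  # outer wall of the bend
        fc = np.array([rad * np.cos(phi_c), rad * np.sin(phi_c), 0.0])
    elif spec.kind == "sidewall_aneurysm":
        tip = spec.sac_center.copy()
        psi = np.pi + rng.uniform(-0.8, 0.8)  # opposite the sac
        dz = rng.uniform(1.5 * r, 3.0 * r)
        fc = np.array(
            [
                inset * np.cos(psi),
                inset * np.sin(psi),
                max(spec.aneurysm_offset - dz, 1.0),
            ]
        )
    else:
        tip = spec.sac_center.copy()
        apex, _, _ = _bifurcation_geometry(spec)
        psi = rng.uniform(0, 2 * np.pi)
        dz = rng.uniform(1.5 * r, 3.0 * r)
        fc = np.array(
            [inset * np.cos(psi), inset * np.sin(psi), max(apex[2] - dz, 1.0)]
        )
    return {"proximal_s": 1.0, "tip": tip, "first_contact": fc}
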