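"""Mandrel shaping transform and bending-template generation.

A microcatheter shaped over a mandrel relaxes ("blunts") after the
mandrel is removed: a bend set to 90 degrees with the mandrel in
relaxes to 45 degrees if the shaping factor f is 2.0.  To obtain the
mandrel-in shape that will relax into the simulated in-vessel pathway,
every joint of the pathway within the shaping length is exaggerated:
the sub-path beyond the joint is rotated rigidly about the joint, around
the cross product of the two adjacent segment directions, by an extra
angle of (f - 1) times the joint angle — so the mandrel-in joint angle
is exactly f times the in-vessel one, while every segment length is
preserved.  The shaped path is then coarsened into a printable
bending template: per-segment length, bend angle, and torsion (the
signed dihedral between consecutive bending planes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .catheter_sim import CatheterPath

__all__ = [
    "ShapingParams",
    "ShapedPath",
    "ShapingTemplate",
    "rotation_matrix",
    "bend_angles",
    "shape_transform",
    "make_template",
    "reconstruct_from_template",
]


@dataclass
class ShapingParams:
    """Shaping factor f >= 1 (mandrel-in angle / relaxed angle) and the
    arc length from the tip that receives the shape, in mm."""

    shaping_factor: float
    shaping_length: float

    def __post_init__(self) -> None:
        if not self.shaping_factor >= 1.0:
            raise ValueError("shaping_factor must be >= 1 (under-shaping not supported)")
        if not self.shaping_length > 0:
            raise ValueError("shaping_length must be positive")


@dataclass
class ShapedPath:
    """The mandrel-in exaggerated path.

    Same point count and per-segment lengths as the input catheter
    path; the tip segment (points 0-1) is the rotation anchor and keeps
    its original orientation.  ``shaped_upto`` is the index of the last
    joint inside the shaping length.
    """

    points: np.ndarray
    shaped_upto: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)


@dataclass
class ShapingTemplate:
    """Per-row bending instructions, tip first.

    Each row covers one straight segment of the coarsened shaped path:
    (segment length mm, bend angle in degrees at the joint at the
    segment's proximal end, torsion in degrees at that joint).  The last
    row has no joint and carries zero bend and torsion; the first bend's
    torsion is zero by convention (it fixes the reference plane).
    """

    rows: np.ndarray  # (n, 3): length_mm, bend_deg, torsion_deg

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float).reshape(-1, 3)


def rotation_matrix(axis, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix for a rotation of ``angle`` radians
    about ``axis`` (right-handed)."""
    axis = np.asarray(axis, dtype=float).reshape(3)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be nonzero")
    k = axis / n
    kx = np.array(
        [[0.0, -k[2], k[1]], [k[2], 0.0, -k[0]], [-k[1], k[0], 0.0]]
    )
    return np.eye(3) + np.sin(angle) * kx + (1.0 - np.cos(angle)) * (kx @ kx)


def _directions(points: np.ndarray) -> np.ndarray:
    seg = np.diff(points, axis=0)
    norms = np.linalg.norm(seg, axis=1)
    if np.any(norms == 0):
        raise ValueError("polyline contains a zero-length segment")
    return seg / norms[:, None]


def bend_angles(points, degrees: bool = True) -> np.ndarray:
    """Angle at each interior joint between adjacent segment directions
    (0 for a straight joint)."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) < 3:
        raise ValueError("need at least 3 points to define a joint")
    u = _directions(points)
    dots = np.clip(np.einsum("ij,ij->i", u[:-1], u[1:]), -1.0, 1.0)
    ang = np.arccos(dots)
    return np.degrees(ang) if degrees else ang


def shape_transform(path: CatheterPath, params: ShapingParams) -> ShapedPath:
    """Exaggerate the in-vessel path into its mandrel-in shape.

    Walking joints from the tip, every joint whose tip-side cumulative
    arc length is within the shaping length is opened from angle theta
    to f*theta by rotating the whole sub-path beyond it rigidly about
    the joint (axis: cross product of the adjacent segment directions,
    extra angle (f-1)*theta).  Straight joints are skipped; a joint
    whose target angle would exceed 180 degrees is clamped to 180 with
    a warning.  Joints beyond the shaping length keep their in-vessel
    geometry.
    """
    pts = np.array(path.points, dtype=float)
    if len(pts) < 2:
        raise ValueError("path must have at least 2 points")
    f = params.shaping_factor
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])  # tip-side arc length

    shaped_upto = 0
    for j in range(1, len(pts) - 1):
        if cum[j] > params.shaping_length + 1e-12:
            break
        shaped_upto = j
        u = pts[j] - pts[j - 1]
        v = pts[j + 1] - pts[j]
        axis = np.cross(u, v)
        norm_axis = np.linalg.norm(axis)
        if norm_axis < 1e-12 * np.linalg.norm(u) * np.linalg.norm(v):
            continue  # straight (or hairpin) joint: no bending plane
        un = u / np.linalg.norm(u)
        vn = v / np.linalg.norm(v)
        theta = float(np.arccos(np.clip(un @ vn, -1.0, 1.0)))
        extra = (f - 1.0) * theta
        if theta + extra > np.pi:
            warnings.warn(
                "shaping factor drives a joint past 180 degrees; clamping",
                stacklevel=2,
            )
            extra = np.pi - theta
        rot = rotation_matrix(axis, extra)
        pts[j + 1 :] = (pts[j + 1 :] - pts[j]) @ rot.T + pts[j]
    return ShapedPath(pts, shaped_upto)


def _rdp(points: np.ndarray, tol: float) -> np.ndarray:
    """Douglas–Peucker polyline simplification (3D, keeps endpoints)."""
    keep = np.zeros(len(points), dtype=bool)
    keep[[0, -1]] = True
    stack = [(0, len(points) - 1)]
    while stack:
        a, b = stack.pop()
        if b - a < 2:
            continue
        chord = points[b] - points[a]
        L = np.linalg.norm(chord)
        rel = points[a + 1 : b] - points[a]
        if L == 0:
            d = np.linalg.norm(rel, axis=1)
        else:
            d = np.linalg.norm(np.cross(rel, chord / L), axis=1)
        i = int(np.argmax(d))
        if d[i] > tol:
            keep[a + 1 + i] = True
            stack.append((a, a + 1 + i))
            stack.append((a + 1 + i, b))
    return points[keep]


def _signed_angle(a: np.ndarray, b: np.ndarray, axis: np.ndarray) -> float:
    """Signed angle from a to b, right-handed about ``axis``."""
    return float(np.arctan2(axis @ np.cross(a, b), a @ b))


def make_template(shaped: ShapedPath, coarsen_tol: float = 0.2) -> ShapingTemplate:
    """Coarsen the shaped path and emit per-joint bending instructions.

    The path is simplified with Douglas–Peucker at ``coarsen_tol`` so
    faceting noise merges into a handful of practical bends.  Torsion at
    a joint is the signed dihedral between its bending plane and the
    previous joint's, right-handed about the shared segment direction;
    the first bending joint's torsion is zero.
    """
    pts = _rdp(shaped.points, coarsen_tol)
    if len(pts) < 2:
        raise ValueError("template needs at least 2 points")
    u = _directions(pts)
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    n_seg = len(seg_len)
    rows = np.zeros((n_seg, 3))
    rows[:, 0] = seg_len
    prev_normal = None
    for k in range(n_seg - 1):
        bend = float(np.arccos(np.clip(u[k] @ u[k + 1], -1.0, 1.0)))
        rows[k, 1] = np.degrees(bend)
        normal = np.cross(u[k], u[k + 1])
        nn = np.linalg.norm(normal)
        if nn < 1e-12:
            continue  # straight joint: keep previous plane
        normal = normal / nn
        if prev_normal is not None:
            rows[k, 2] = np.degrees(_signed_angle(prev_normal, normal, u[k]))
        prev_normal = normal
    return ShapingTemplate(rows)


def reconstruct_from_template(template: ShapingTemplate) -> np.ndarray:
    """Rebuild a polyline from a template (up to rigid motion).

    Starts at the origin heading +x with the bending plane normal +z;
    each row advances by its segment length, then applies the torsion
    (rotating the plane normal about the current direction) and the
    bend (rotating the direction about the plane normal).
    """
    rows = template.rows
    p = np.zeros(3)
    d = np.array([1.0, 0.0, 0.0])
    normal = np.array([0.0, 0.0, 1.0])
    out = [p.copy()]
    for length, bend_deg, torsion_deg in rows:
        p = p + length * d
        out.append(p.copy())
        if bend_deg != 0.0:
            normal = rotation_matrix(d, np.radians(torsion_deg)) @ normal
            d = rotation_matrix(normal, np.radians(bend_deg)) @ d
    return np.asarray(out)
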