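"""Virtual microcatheter growth inside the vessel lumen.

The virtual catheter grows from the tip (usually the aneurysm sac
centroid) toward the proximal end of the anticipated pathway.  Trial
points are generated one by one along the direction defined by the
previous two points; each trial point is collision-checked against the
vessel wall by ray casting, and an out-of-vessel point is corrected by
intersecting the line to its nearest centerline neighbor with the wall
and pulling it a small offset back inside.  The growth direction is
reset to the realized step after every correction.  Growth stops once
the trial point projects onto the centerline at (or proximal to) the
picked proximal arc-length position.

The result is a polyline of adjacent segments — the anticipated
microcatheter pathway as it would sit in the vessel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .centerline import Centerline
from .segmentation import SurfaceMesh

__all__ = [
    "PickedPoints",
    "GrowthParams",
    "CatheterPath",
    "RayCaster",
    "NonConvergentGrowthError",
    "point_in_vessel",
    "segment_first_intersection",
    "nearest_on_centerline",
    "grow_catheter",
]

# default cast direction: an unstructured unit vector so axis-aligned
# mesh edges from marching cubes are not grazed systematically
_DEFAULT_DIR = np.array([3.0, 2.0, 1.0]) / np.sqrt(14.0)
_BARY_TOL = 1e-9


class NonConvergentGrowthError(RuntimeError):
    """Growth exhausted ``max_points`` before reaching the proximal pick.

    The partial path is attached as ``partial_path``.
    """

    def __init__(self, msg: str, partial_path: "CatheterPath"):
        super().__init__(msg)
        self.partial_path = partial_path


@dataclass
class PickedPoints:
    """The three user picks that define the anticipated pathway.

    ``proximal_s`` is the arc-length position (mm) of the proximal end
    on the centerline; ``tip`` is the catheter tip target (usually the
    sac centroid); ``first_contact`` is the anticipated first
    wall-contact point along the distal-to-proximal direction from the
    tip.  The first contact pick constrains only the initial growth
    direction; it is not enforced as a path point.
    """

    proximal_s: float
    tip: np.ndarray
    first_contact: np.ndarray

    def __post_init__(self) -> None:
        self.tip = np.asarray(self.tip, dtype=float).reshape(3)
        self.first_contact = np.asarray(self.first_contact, dtype=float).reshape(3)
        self.proximal_s = float(self.proximal_s)


@dataclass
class GrowthParams:
    """Free parameters of the growth loop.

    step
        Trial-point spacing in mm (default 0.3, roughly the scale of a
        microcatheter tip).
    wall_offset
        How far inside the wall a corrected point is pulled back, mm.
    max_points
        Hard bound on the number of generated points.
    arrival_tol
        Arc-length tolerance (mm) for "reaching" the proximal pick.
    """

    step: float = 0.3
    wall_offset: float = 0.05
    max_points: int = 2000
    arrival_tol: float = 1.0

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ValueError("step must be positive")
        if not 0 < self.wall_offset < self.step:
            raise ValueError("wall_offset must lie in (0, step)")
        if self.max_points < 2:
            raise ValueError("max_points must allow at least two points")


@dataclass
class CatheterPath:
    """The grown catheter polyline, tip first.

    ``corrected[i]`` records whether point i was produced by a wall
    correction rather than a free step.
    """

    points: np.ndarray
    corrected: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.corrected is None:
            self.corrected = np.zeros(len(self.points), dtype=bool)
        self.corrected = np.asarray(self.corrected, dtype=bool).ravel()
        if len(self.corrected) != len(self.points):
            raise ValueError("corrected flags must match point count")

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def total_length(self) -> float:
        return float(self.segment_lengths.sum())


class RayCaster:
    """Möller–Trumbore ray/segment intersection against a triangle soup.

    Precomputes per-face edge vectors once so repeated queries during
    growth are a single vectorized pass over the faces.  Containment is
    decided by ray-crossing parity; degenerate casts (a hit grazing a
    triangle edge or vertex, or a near-parallel face) are re-cast along
    a fresh pseudo-random direction from a seeded generator.
    """

    def __init__(self, mesh: SurfaceMesh, require_watertight: bool = True):
        if require_watertight and not mesh.is_watertight:
            raise ValueError("containment queries require a watertight mesh")
        tri = mesh.vertices[mesh.faces]
        self._v0 = tri[:, 0]
        self._e1 = tri[:, 1] - tri[:, 0]
        self._e2 = tri[:, 2] - tri[:, 0]
        self._scale = float(np.abs(tri).max()) or 1.0

    def _cast(self, origin: np.ndarray, direction: np.ndarray):
        """All positive-t intersections of the ray with the faces.

        Returns (t_values, degenerate): t values where the ray crosses a
        face, and whether any crossing was too close to a face boundary
        (or a face too close to parallel) for the parity count to be
        trusted.
        """
        pvec = np.cross(direction, self._e2)
        det = np.einsum("ij,ij->i", self._e1, pvec)
        near_parallel = np.abs(det) < 1e-12 * self._scale
        safe_det = np.where(near_parallel, 1.0, det)
        tvec = origin - self._v0
        u = np.einsum("ij,ij->i", tvec, pvec) / safe_det
        qvec = np.cross(tvec, self._e1)
        v = np.einsum("j,ij->i", direction, qvec) / safe_det
        t = np.einsum("ij,ij->i", self._e2, qvec) / safe_det
        inside = (
            ~near_parallel
            & (u >= -_BARY_TOL)
            & (v >= -_BARY_TOL)
            & (u + v <= 1.0 + _BARY_TOL)
            & (t > 1e-12)
        )
        edge_tol = 1e-7
        grazing = inside & (
            (u < edge_tol) | (v < edge_tol) | (u + v > 1.0 - edge_tol)
        )
        return t[inside], bool(grazing.any())

    def contains(self, point: np.ndarray, seed: int = 0) -> bool:
        """Point-in-mesh by ray-crossing parity, with up to 5 seeded
        re-casts when a cast is degenerate."""
        point = np.asarray(point, dtype=float).reshape(3)
        if not np.all(np.isfinite(point)):
            raise ValueError("point must be finite")
        direction = _DEFAULT_DIR
        rng = None
        for _ in range(6):
            t, degenerate = self._cast(point, direction)
            if not degenerate:
                return len(t) % 2 == 1
            if rng is None:
                rng = np.random.default_rng(seed)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
        return len(t) % 2 == 1  # all retries grazed; accept last parity

    def contains_many(self, points: np.ndarray, seed: int = 0) -> np.ndarray:
        return np.array([self.contains(p, seed=seed) for p in np.asarray(points)])

    def segment_hit(self, p: np.ndarray, q: np.ndarray):
        """First wall crossing along the segment p→q, or None."""
        p = np.asarray(p, dtype=float).reshape(3)
        q = np.asarray(q, dtype=float).reshape(3)
        d = q - p
        if not np.linalg.norm(d) > 0:
            raise ValueError("segment endpoints must differ")
        t, _ = self._cast(p, d)
        t = t[t <= 1.0 + 1e-12]
        if len(t) == 0:
            return None
        return p + float(t.min()) * d


def point_in_vessel(mesh: SurfaceMesh, point, seed: int = 0) -> bool:
    """True iff a ray from ``point`` crosses the vessel surface an odd
    number of times (watertight mesh required)."""
    return RayCaster(mesh).contains(point, seed=seed)


def segment_first_intersection(mesh: SurfaceMesh, p, q):
    """Nearest-to-``p`` intersection of segment [p, q] with the surface,
    or None when the segment does not cross it."""
    return RayCaster(mesh, require_watertight=False).segment_hit(p, q)


def nearest_on_centerline(centerline: Centerline, point):
    """Centerline sample closest to ``point``; ties break to the
    smaller index.  Returns (index, point, arc_length)."""
    point = np.asarray(point, dtype=float).reshape(3)
    diff = centerline.points - point
    i = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
    return i, centerline.points[i].copy(), float(centerline.arc_length[i])


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction")
    return v / n


def _advance_inside(
    caster: RayCaster, prev: np.ndarray, target: np.ndarray, step: float, seed: int
) -> np.ndarray:
    """Farthest point toward ``target`` that is inside the mesh and at
    most ``step`` from ``prev`` (bisection from the known-inside prev)."""
    d = target - prev
    dist = np.linalg.norm(d)
    if dist == 0:
        return prev.copy()
    d = d / dist
    hi = min(step, dist)
    if caster.contains(prev + hi * d, seed=seed):
        return prev + hi * d
    lo = 0.0
    for _ in range(24):
        mid = 0.5 * (lo + hi)
        if caster.contains(prev + mid * d, seed=seed):
            lo = mid
        else:
            hi = mid
    return prev + lo * d


def grow_catheter(
    mesh: SurfaceMesh,
    centerline: Centerline,
    picks: PickedPoints,
    params: GrowthParams = None,
    seed: int = 0,
    caster: "RayCaster" = None,
) -> CatheterPath:
    """Grow the virtual microcatheter from the tip to the proximal pick.

    Point 0 is the tip; point 1 steps toward the first-contact pick;
    each later trial point continues along the direction of the previous
    two points.  A trial point that fails the in-vessel test is replaced
    by the wall intersection of its line to the nearest centerline
    neighbor, pulled ``wall_offset`` inside, and the growth direction is
    reset to the realized step.  Termination: the trial point's
    projected centerline arc length falls within ``arrival_tol`` of
    ``proximal_s`` (or below it).

    Raises
    ------
    ValueError
        If the tip is outside the vessel.
    NonConvergentGrowthError
        If ``max_points`` is exhausted before arrival; the partial path
        is attached to the exception.
    """
    if params is None:
        params = GrowthParams()
    if caster is None:
        caster = RayCaster(mesh)
    tip = picks.tip
    if not caster.contains(tip, seed=seed):
        raise ValueError("tip pick lies outside the vessel mesh")
    step, offset = params.step, params.wall_offset

    points = [tip.copy()]
    corrected = [False]
    direction = _unit(picks.first_contact - tip)
    prev = tip

    while len(points) < params.max_points:
        trial = prev + step * direction
        was_corrected = False
        if not caster.contains(trial, seed=seed):
            was_corrected = True
            _, nn, _ = nearest_on_centerline(centerline, trial)
            hit = caster.segment_hit(trial, nn) if np.any(nn != trial) else None
            if hit is not None:
                cand = hit + offset * _unit(nn - hit)
            else:
                # faceting let the segment slip through; the centerline
                # neighbor itself is guaranteed interior
                cand = nn
            if (
                np.linalg.norm(cand - prev) > step + 1e-9
                or not caster.contains(cand, seed=seed)
            ):
                cand = _advance_inside(caster, prev, cand, step, seed)
            trial = cand
            delta = trial - prev
            if np.linalg.norm(delta) > 1e-12:
                direction = _unit(delta)
        points.append(trial.copy())
        corrected.append(was_corrected)
        _, _, s = nearest_on_centerline(centerline, trial)
        if s <= picks.proximal_s + params.arrival_tol:
            return CatheterPath(np.asarray(points), np.asarray(corrected))
        prev = trial

    partial = CatheterPath(np.asarray(points), np.asarray(corrected))
    raise NonConvergentGrowthError(
        "non-convergent growth: max_points reached before the proximal pick",
        partial,
    )
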