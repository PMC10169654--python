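"""Centerline extraction from the proximal inlet to the aneurysm.

The centerline is the reference polyline for the catheter growth
algorithm: every wall correction pulls the trial point back toward its
nearest centerline neighbor.  It is computed as a shortest path on the
26-connected foreground voxel graph whose edge cost penalizes proximity
to the wall (step length divided by the interior distance map), the
classic maximal-inscribed-sphere centrality surrogate.  The user
supplies two clicked points, at the proximal inlet and at the aneurysm
dome; both are snapped to the nearest foreground voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "Centerline",
    "NoPathError",
    "interior_distance_map",
    "compute_centerline",
    "resample_smooth",
]

# 26-neighborhood, one representative per symmetric pair
_OFFSETS = np.array(
    [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
        if (di, dj, dk) > (0, 0, 0)
    ]
)


class NoPathError(ValueError):
    """The two clicks lie in disconnected foreground components."""


@dataclass
class Centerline:
    """Ordered polyline with arc-length parameterization.

    Index 0 is the proximal inlet; the last point is the distal end
    (aneurysm dome click or sac centroid).  ``local_radius`` is the
    distance from each point to the nearest vessel wall.
    """

    points: np.ndarray
    arc_length: np.ndarray
    local_radius: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.arc_length = np.asarray(self.arc_length, dtype=float).ravel()
        self.local_radius = np.asarray(self.local_radius, dtype=float).ravel()
        n = len(self.points)
        if len(self.arc_length) != n or len(self.local_radius) != n:
            raise ValueError("field lengths disagree")
        if n >= 2 and np.any(np.diff(self.arc_length) <= 0):
            raise ValueError("arc_length must be strictly increasing")

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    @classmethod
    def from_points(
        cls, points: np.ndarray, local_radius: np.ndarray | None = None
    ) -> "Centerline":
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        arc = _cumulative_arc(points)
        if local_radius is None:
            local_radius = np.full(len(points), np.nan)
        return cls(points, arc, local_radius)


def _cumulative_arc(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def interior_distance_map(mask: np.ndarray, spacing) -> np.ndarray:
    """Euclidean distance (mm) from each foreground voxel to the nearest
    background voxel; zero outside the mask."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    return ndimage.distance_transform_edt(mask, sampling=np.asarray(spacing, float))


def _snap_to_foreground(mask, spacing, origin, click) -> tuple[int, int, int]:
    """Nearest foreground voxel to a world-mm click; ties go to the
    lowest linear (C-order) index."""
    fg = np.argwhere(mask)
    centers = origin + fg * spacing
    d2 = np.einsum("ij,ij->i", centers - click, centers - click)
    return tuple(fg[int(np.argmin(d2))])


def compute_centerline(
    mask: np.ndarray,
    spacing,
    inlet_click,
    dome_click,
    origin=(0.0, 0.0, 0.0),
    step: float = 0.5,
    smooth_window: int = 5,
    eps_factor: float = 0.1,
) -> Centerline:
    """Shortest centrality-weighted path between two clicked points.

    The edge between adjacent foreground voxels u, v costs
    ``len(u,v) * (1/(D(u)+eps) + 1/(D(v)+eps)) / 2`` where D is the
    interior distance map — symmetric in u and v, so swapping the clicks
    reverses the path.  ``eps = eps_factor * min(spacing)`` guards the
    division near the wall.  The raw voxel path is smoothed with a short
    moving average and resampled at uniform arc length ``step``.
    """
    mask = np.asarray(mask).astype(bool)
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    inlet_click = np.asarray(inlet_click, dtype=float)
    dome_click = np.asarray(dome_click, dtype=float)

    dist = interior_distance_map(mask, spacing)
    eps = eps_factor * float(spacing.min())

    src = _snap_to_foreground(mask, spacing, origin, inlet_click)
    dst = _snap_to_foreground(mask, spacing, origin, dome_click)
    if src == dst:
        raise ValueError("inlet and dome clicks snap to the same voxel")

    lin = np.full(mask.shape, -1, dtype=np.int64)
    nfg = int(mask.sum())
    lin[mask] = np.arange(nfg)
    inv_d = np.zeros(mask.shape)
    inv_d[mask] = 1.0 / (dist[mask] + eps)

    rows, cols, weights = [], [], []
    for off in _OFFSETS:
        a_sl = tuple(
            slice(max(o, 0), mask.shape[ax] + min(o, 0)) for ax, o in enumerate(-off)
        )
        b_sl = tuple(
            slice(max(o, 0), mask.shape[ax] + min(o, 0)) for ax, o in enumerate(off)
        )
        both = mask[a_sl] & mask[b_sl]
        if not both.any():
            continue
        ia = lin[a_sl][both]
        ib = lin[b_sl][both]
        length = float(np.linalg.norm(off * spacing))
        w = length * 0.5 * (inv_d[a_sl][both] + inv_d[b_sl][both])
        rows.append(ia)
        cols.append(ib)
        weights.append(w)
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nfg, nfg),
    )

    isrc, idst = int(lin[src]), int(lin[dst])
    dists, pred = dijkstra(
        graph, directed=False, indices=isrc, return_predecessors=True
    )
    if not np.isfinite(dists[idst]):
        raise NoPathError("no path: clicks lie in disconnected components")

    chain = [idst]
    while chain[-1] != isrc:
        chain.append(int(pred[chain[-1]]))
    chain.reverse()
    fg = np.argwhere(mask)
    voxel_path = fg[np.asarray(chain)]
    points = origin + voxel_path * spacing

    cl = Centerline.from_points(points)
    cl = resample_smooth(cl, step=step, smooth_window=smooth_window)
    radius = _sample_map(dist, spacing, origin, cl.points)
    return Centerline(cl.points, cl.arc_length, radius)


def _sample_map(volume_data, spacing, origin, points) -> np.ndarray:
    idx = (np.asarray(points) - origin) / spacing
    return ndimage.map_coordinates(
        np.asarray(volume_data, dtype=float), idx.T, order=1, mode="nearest"
    )


def resample_smooth(
    centerline: Centerline, step: float, smooth_window: int = 5
) -> Centerline:
    """Moving-average smoothing followed by arc-length-uniform resampling.

    Endpoints are preserved exactly.  A ``step`` at or beyond the total
    length degenerates to the two endpoints.
    """
    if not step > 0:
        raise ValueError("step must be positive")
    pts = centerline.points
    if len(pts) > 2 and smooth_window > 1:
        sm = ndimage.uniform_filter1d(pts, size=int(smooth_window), axis=0, mode="nearest")
        sm[0], sm[-1] = pts[0], pts[-1]
        pts = sm
    arc = _cumulative_arc(pts)
    total = arc[-1]
    if step >= total:
        new_arc = np.array([0.0, total])
    else:
        n = int(np.floor(total / step)) + 1
        new_arc = np.linspace(0.0, total, max(n, 2))
    new_pts = np.column_stack(
        [np.interp(new_arc, arc, pts[:, ax]) for ax in range(3)]
    )
    new_pts[0], new_pts[-1] = pts[0], pts[-1]
    radius = np.interp(new_arc, centerline.arc_length, centerline.local_radius)
    return Centerline(new_pts, _cumulative_arc(new_pts), radius)
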