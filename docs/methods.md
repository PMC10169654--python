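# Methods

This note records the models, parameter choices and numerical decisions
behind `mandrelsim`, and what the synthetic validation does and does not
demonstrate.

## Coordinate conventions

All world coordinates are millimeters, RAS orientation. Voxel `(i,j,k)`
of a volume sits at `origin + index * spacing` (voxel centers, 0-based).
NIfTI affines must be axis-aligned (orthogonal, no shear); geometry is
converted once at ingestion. Mesh faces are wound counter-clockwise
seen from outside (outward normals, positive signed volume).

## Segmentation

The lumen is segmented in two steps. A global intensity threshold
(default 50, halfway between the phantom contrast levels 0/100)
initializes the front, restricted to the largest 26-connected component
to discard noise speckles. The front is then evolved by a two-phase
region-based level set (morphological Chan–Vese): each iteration moves
the interface to better separate the mean intensities inside and
outside, followed by `smoothing` passes of a morphological curvature
operator. Defaults: 25 iterations, curvature weight 1. The curvature
weight trades noise robustness against shrinkage of thin tubes — on a
noiseless volume a weight of 0 leaves a correct mask exactly fixed,
while weight 1 erodes a 5-voxel-radius tube measurably; keep the weight
at 1 for noisy data and reduce it for clean, thin-vessel volumes.

The implementation of the morphological scheme in scikit-image carries
an internal alternating-operator phase across calls; `levelset_refine`
resets it so identical inputs always give identical masks.

`extract_surface` runs marching cubes at the 0.5 level on the
zero-padded mask after a light Gaussian blur (σ = 0.6 voxel). The blur
removes the voxel staircase: without it the isosurface area of a ball
is ~9% above the true value, with it +1.2% (volume −1.9%) while the
surface moves less than half a voxel. Padding guarantees a closed
surface; the result is watertight with outward normals.

A spherical region-of-interest crop keeps faces whose centroids fall in
the sphere. Cropping is bookkeeping/visualization only: the output is
flagged `open_boundary` and refused by containment queries, because
ray-parity tests are undefined on open meshes. Collision detection
always runs against the full watertight mesh. Cropping before or after
centerline computation is a pipeline-config choice.

## Centerline

The centerline from the proximal inlet click to the aneurysm dome click
is the shortest path on the 26-connected foreground voxel graph with
symmetric edge cost

    cost(u, v) = |u − v| · ( 1/(D(u)+ε) + 1/(D(v)+ε) ) / 2,

where `D` is the Euclidean distance transform (mm to the nearest
background voxel) and ε = 0.1·min(spacing) guards the division at the
wall. Penalizing wall proximity drives the path onto the maximal
inscribed spheres, i.e. the lumen axis; the symmetric form makes the
path invariant (as a point set) under swapping the clicks. Clicks snap
to the nearest foreground voxel, ties broken by lowest linear (C-order)
index for determinism.

The raw voxel path is smoothed with a 5-point moving average (endpoints
pinned) and resampled at uniform 0.5 mm arc length — finer than the
catheter growth step so nearest-neighbor queries are well resolved. On
phantoms this recovers a straight cylinder's axis to well under one
voxel and a 90° arc's length to ~3% (the residual is half-voxel endpoint
snapping plus smoothing shrinkage; both scale with voxel size).
`local_radius` is the distance map interpolated at the samples. The
centerline may terminate at the dome click or be redirected to the sac
centroid (`end_at` config); default is the click.

## Catheter growth

The virtual catheter is a polyline grown tip-first. Inputs: the
watertight mesh, the centerline, and three picks — the proximal
arc-length position `proximal_s`, the tip (usually the sac centroid),
and the anticipated first wall-contact point, which fixes only the
initial direction. Each trial point continues the direction of the
previous two points with step 0.3 mm (≈ microcatheter tip scale; small
enough that one step's wall penetration is sub-voxel).

Collision detection is point-in-mesh by ray-crossing parity: a single
ray per query, Möller–Trumbore intersection against all faces,
vectorized. A cast whose hit grazes a triangle edge/vertex (barycentric
coordinate within 1e-7 of the boundary) or meets a near-parallel face
is re-cast along a pseudo-random direction from a generator seeded by
the caller, up to 5 retries — so degenerate-hit resolution is
deterministic. The default cast direction is deliberately unstructured
(normalized (3,2,1)) because marching-cubes meshes have grid-aligned
edges that axis-aligned rays would graze systematically.

A trial point that leaves the lumen is corrected: the segment from the
trial point to its nearest centerline sample is intersected with the
wall, and the point is placed `wall_offset` = 0.05 mm inside the
crossing, which strictly passes containment and avoids boundary-parity
ambiguity. If faceting lets the segment slip through without a
crossing, the centerline sample itself (guaranteed interior) is the
fallback. If the corrected point would exceed one step from its
predecessor, it is pulled back along the same direction (bisecting from
the known-interior predecessor) so the step bound and the interior
guarantee both hold unconditionally. After a correction the growth
direction resets to the realized step direction.

Growth terminates when the trial point's nearest-neighbor projection
onto the centerline has arc length within `arrival_tol` = 1 mm of
`proximal_s` (or below). Note the *lateral* offset of the arrival point
from the centerline is bounded only by the local lumen radius — the
arriving catheter hugs the wall, as a real one does. `max_points`
(default 2000) bounds non-convergent growth; exhaustion raises an error
carrying the partial path.

## Shaping transform

Let the in-vessel path have joints with angles θ_j (angle between
adjacent segment direction vectors, `arccos` of the clamped dot
product). Walking joints from the tip while the tip-side cumulative arc
length is within the shaping length, the sub-path beyond joint j is
rotated rigidly about the joint by the Rodrigues rotation with axis
u × v (the adjacent direction vectors' cross product) and angle
(f − 1)·θ_j. The resulting joint angle is exactly f·θ_j, all segment
lengths are preserved exactly, joints on either side are unchanged, and
the tip segment keeps its original orientation (rotation anchor). This
is the only application order with an exact per-joint scaling
invariant, and it reproduces the defining example 45° → 90° at f = 2.
Straight joints (zero cross product) are skipped; a joint whose target
angle would pass 180° is clamped there with a warning (a physical
mandrel cannot bend past a hairpin). f < 1 (under-shaping) is rejected.
Joints beyond the shaping length keep their in-vessel geometry; a
`straighten` variant was considered and left out (least surprise).

The bending template coarsens the shaped path by Douglas–Peucker
(default tolerance 0.2 mm, merging faceting noise into a handful of
practical bends) and emits per-segment rows: length, bend angle at the
joint at the segment's proximal end, and torsion — the signed dihedral
between consecutive bending planes, right-handed about the shared
segment direction, with the first bending joint's torsion zero (it
fixes the reference plane). Bending-plane normals are oriented
(u × v), so a planar path that alternates bend sense shows a half-turn
torsion flip (physically: flip the mandrel over); this orientation is
what makes the template→polyline reconstruction exact up to a rigid
motion, which is verified in the tests.

## Cohort statistics

`proportion` reports 100·n/d rounded to two decimals. `pearson_chi2` is
the 1-df Pearson test without Yates continuity correction — the
convention consistent with the reference cohort's printed p = 0.015 for
reshaping rates 12/55 vs 22/50. `spearman_rho` uses average ranks for
ties. The chi-squared p is validated against a label-permutation null:
because that null is discrete, the asymptotic p is checked to lie
inside the bracket [P(stat > obs), P(stat ≥ obs)] rather than to match
a single permutation p. Tests for continuous outcomes are deliberately
not provided: they need per-patient data that summary tables cannot
supply.

## Phantoms — what they emulate and what they do not

Phantoms are unions of closed-form primitives — capped cylinder, torus
arc with flat angular caps, sphere, capsules for bifurcation branches —
described by a signed interior depth (max over primitive depths,
positive inside). Defaults model a cerebral-scale geometry: parent
artery radius 2 mm, length 40 mm, sac radius 3 mm seated with its
center at tube_radius + sac_radius/2 from the axis (a wide ostium),
0.4 mm isotropic voxels, foreground/background intensities 100/0 with
optional seeded additive Gaussian noise (σ = 20 in the noisy test
condition). The voxel grid is staggered half a voxel off the geometry's
symmetry planes, as real scan grids are; sampling a flat cap exactly on
a voxel-center plane would erode the mask by a voxel there. The mesh is
marching cubes at level 0 of the depth field on a grid of spacing
min(voxel, r/4) — sub-voxel accurate and watertight by construction.
The truth centerline is the analytic axis polyline (inlet → sac
centroid for aneurysm kinds), end points inset 1 µm so all are strictly
interior.

The phantoms give every stage a closed-form oracle, but they are not
angiography: no contrast inhomogeneity or partial-volume blur, no
imaging artifacts, no vessel taper, tortuosity or branching trees, and
an idealized spherical sac. Passing the suite therefore shows the
geometric algorithms are correct and self-consistent under the stated
contrast model — not that segmentation parameters transfer to clinical
3DRA, and no clinical outcome (reshaping rates, fluoroscopy time,
occlusion grade) is reproduced computationally beyond the printed-count
arithmetic above.

## Problem sizes and determinism

Default test geometries run in seconds: volumes of order 30×30×110
voxels, meshes of ~5–10 k faces, catheter paths of ~50–150 points; the
Monte-Carlo containment cross-checks use 1000 points per phantom. All
randomness (phantom noise, ray re-cast directions, pick variants) flows
from explicit integer seeds; pipeline reruns with the same seed produce
byte-identical CSV artifacts, recorded with SHA-256 checksums in the
run manifest.
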