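# mandrelsim

Virtual microcatheter shaping for endovascular aneurysm embolization.

Before coiling an intracranial aneurysm, the interventionalist bends the
distal tip of the microcatheter over a stiff mandrel (fixed by steaming)
so that, once advanced through the parent artery, the tip seats stably
inside the aneurysm sac. Choosing that bend by eye from angiography is
trial-and-error; a poorly shaped catheter needs to be withdrawn and
reshaped mid-procedure. `mandrelsim` plans the shape geometrically from
a 3D vessel image:

1. **Segment** the vessel lumen (threshold + region-based level set) and
   reconstruct a watertight surface mesh (marching cubes).
2. **Centerline** from the proximal inlet to the aneurysm, computed as a
   shortest path on the foreground voxel graph with edge cost
   `len / (D + ε)`, where `D` is the Euclidean distance-to-wall map —
   the classic maximal-inscribed-sphere centrality surrogate.
3. **Grow** the virtual catheter from the tip (usually the sac centroid)
   toward the proximal pick: trial points advance one step at a time
   along the direction of the previous two points; each is
   collision-checked by ray casting (Möller–Trumbore + crossing parity),
   and an escaping point is corrected to the wall intersection of its
   line to the nearest centerline neighbor, pulled a small offset back
   inside, resetting the growth direction.
4. **Shape**: every joint angle θ of the in-vessel path within the
   shaping length is exaggerated to f·θ by rigidly rotating the distal
   sub-path about the joint by (f − 1)·θ around the cross product of the
   adjacent segment directions. The shaping factor f ≥ 1 models the
   blunting of the bend after the mandrel is removed: a 90° mandrel-in
   bend relaxes to 45° when f = 2. The shaped path is coarsened
   (Douglas–Peucker) into a printable bending template of
   (segment length, bend angle, torsion) rows.

Because no public angiography accession accompanies this method, the
package ships a `phantom` module generating parametric vessel+aneurysm
geometries (straight/bent tubes, sidewall and bifurcation aneurysms)
with closed-form containment, surface and centerline ground truth —
every pipeline stage is validated against analytic oracles. A
`cohort_stats` module provides the validation arithmetic used when
comparing a software-assisted against a manually shaped cohort
(percentages from counts, Pearson chi-squared without continuity
correction, Spearman rank correlation).

## Worked example

The defining behavior of the shaping transform — a 45° in-vessel bend
doubled by shaping factor 2.0:

```python
import numpy as np
import mandrelsim as ms

a = np.radians(45.0)
path = ms.CatheterPath([[0, 0, 0], [10, 0, 0],
                        [10 + 10*np.cos(a), 10*np.sin(a), 0]])
shaped = ms.shape_transform(path, ms.ShapingParams(2.0, path.total_length))
print("in-vessel bend:", ms.bend_angles(path.points)[0])
print("mandrel-in bend:", ms.bend_angles(shaped.points)[0])
```

prints

```
in-vessel bend: 45.0
mandrel-in bend: 89.99999999999999
```

meaning the mandrel template must hold a 90° bend for the catheter to
relax into the desired 45° once the mandrel is removed. Segment lengths
are preserved exactly (the rotations are rigid).

End to end on a synthetic sidewall aneurysm (2 mm parent artery, 3 mm
sac), from the shell:

```sh
mandrelsim run --out demo_run --seed 0
```

writes the volume, mesh, centerline, catheter path, shaped path and the
template `demo_run/template.csv`:

```
segment_length_mm  bend_deg  torsion_deg
             7.45     94.22          0.0
             6.23     21.55        -18.0
            12.00      0.00          0.0
```

read tip-first: hold 7.45 mm straight from the tip, bend 94.2° (which
relaxes to ~47° at f = 2), continue 6.23 mm, rotate the bending plane
−18° about the catheter axis and bend 21.5°, then the remaining 12 mm
stay straight. The run manifest records parameters, seed, and per-file
checksums; reruns with the same seed are byte-identical.

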