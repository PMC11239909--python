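# junctshape

3D morphometry and abundance estimation of **ER–nuclear-envelope membrane
junctions** from segmented electron-tomography surfaces.

The endoplasmic reticulum (ER) is continuous with the outer nuclear membrane
(ONM), but the junctions that connect them are rare and tiny: constricted,
hourglass-shaped necks on the order of 10–20 nm — quite unlike the broad,
cone-based junctions inside the ER network. Quantifying them requires
measuring neck geometry on triangulated membrane meshes and counting
junctions per unit nuclear-envelope (NE) area. `junctshape` implements that
pipeline for electron microscopists and image analysts working with
segmented tomograms (or FIB-SEM volumes), and ships synthetic junction
generators with closed-form ground truth so every stage is testable without
any raw data.

## What it computes

For a junction annotated with a base point (on the mean ONM plane) and an
axis, measured on a series of planar cross-sections along a centreline:

* **neck**: the minimum-area cross-section within a window (default 25 nm)
  of the junction base;
* **width** W = (major + minor)/2 of the neck's minimum-area *rotated*
  bounding rectangle; **aspect ratio** AR = major/minor;
* **length** L = L1 + L2, the distances from the neck to the nearest sampled
  section with a 1.2-fold larger area toward the NE (L1) and the ER (L2);
* **shrinkage correction**: native = measured / (1 − f), default f = 0.17
  for plastic-embedded specimens;
* **abundance**: junction frequency per μm² of screened NE (NE area from a
  stitched contour mesh or from Σ length × depth), extrapolated to junctions
  per nucleus via the total NE surface (400 μm² telophase / 800 μm²
  interphase);
* **stereology**: uniformly spread spherical inspection regions on a
  segmented nuclear surface (seeded farthest-point sampling).

See `docs/methods.md` for the model, defaults and numerical choices.

## Worked example

```python
import numpy as np
from junctshape import (
    SyntheticJunctionSpec, make_hourglass, JunctionAnnotation,
    measure_junction, correct_shrinkage,
    junction_frequency, estimate_total, area_from_length_depth,
)

# a constricted ER-NE junction: hyperboloid neck, 20 nm across, c = 10 nm
spec = SyntheticJunctionSpec(neck_diameter=20.0, neck_scale=10.0)
mesh, truth = make_hourglass(spec)
ann = JunctionAnnotation("j0", base_point=[0, 0, 0], axis_hint=[0, 0, 1])
res = measure_junction(mesh, ann, step=0.5, window=25.0, mode="fixed")
print(f"W = {res.width_W:.2f} nm   (truth {truth.true_width:.2f})")
print(f"L = {res.length_L:.2f} nm   (truth {truth.true_length:.2f})")
print(f"native W = {correct_shrinkage(res.width_W):.1f} nm")

# junction frequency: 23 junctions over 178 um^2 of screened NE
anns = [JunctionAnnotation(f"j{i}", [i * 1e3, 0, 0], [0, 0, 1]) for i in range(23)]
freq = junction_frequency(anns, area_from_length_depth([(178.0, 1.0)]))
per_nucleus, one_sf = estimate_total(freq, total_ne_area_um2=800.0)
print(f"frequency = {freq.frequency_per_um2:.4f} /um^2 (reported {freq.reported})")
print(f"per nucleus = {per_nucleus:.1f} (~{one_sf:.0f})")
```

prints

```
W = 20.00 nm   (truth 20.00)
L = 9.00 nm   (truth 8.94)
native W = 24.1 nm
frequency = 0.1292 /um^2 (reported 0.13)
per nucleus = 103.4 (~100)
```

The measured width matches the generator's ground truth to well under a
percent; the length is quantized to the 0.5 nm section step (analytic value
2c√0.2 ≈ 8.94 nm). The frequency example reproduces the published worked
numbers: 23/178 ≈ 0.13 μm⁻², about 100 junctions on an interphase nucleus.

A thin CLI wraps the same functions:

```sh
junctshape generate --kind hourglass --seed 3 --out out/
junctshape measure --mesh out/hourglass.obj --annotations ann.json --out results.csv
junctshape abundance --annotations scene.json --ne-area-mode length_depth \
    --components "178,1" --total-area 800 --out freq.json
junctshape stereology --mask nucleus.tif --n 52 --radius 900 --seed 7 --out rois.json
```

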