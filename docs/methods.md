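# Methods

`junctshape` quantifies the 3D geometry and abundance of membrane junctions
between the endoplasmic reticulum (ER) and the nuclear envelope (NE) on
triangulated surfaces derived from electron-tomography segmentations. This
note records the measurement model, the synthetic geometries used to validate
it, the numerical choices, and what the validation does and does not show.

## The measurement model

A junction is a narrow membrane neck connecting the ER to the outer nuclear
membrane (ONM). Its geometry is read off a series of planar cross-sections
taken along a centreline starting at the annotated *base point* (where the
junction meets the mean ONM plane) and heading into the ER:

* **Section series.** Stations s = 0, Δs, 2Δs, … (default Δs = 0.5 nm, valid
  range (0, 5] nm) along the centreline. In *fixed* mode all cutting planes
  share the annotated axis. In *adaptive* mode the next plane origin is the
  previous section's area centroid advanced along the current axis, and the
  axis is re-estimated from the smoothed centroid direction (lever arm of 4
  stations, damped 70/30 blend, tilt capped at 15° per step). The adaptive
  rule reproduces an operator-drawn centreline objectively: on a 90° elbow
  tube it holds section areas constant to < 1 %, where a fixed axis errs by
  > 70 %. If a tilted plane escapes through an open mesh boundary the step is
  retried along the original axis before the series is declared lost.
* **Neck.** The minimum-area section within a window (default 25 nm) of the
  base. Because sections are sampled far more finely than tracing noise is
  correlated, a raw argmin would select downward noise excursions; the area
  profile is therefore smoothed with a ±3 nm moving average (the scale at
  which tracing error decorrelates) and the station is refined by a local
  least-squares parabola on the raw areas — near its waist a smooth neck has
  a quadratic area profile, and a fitted vertex does not correlate with any
  single section's noise. On noiseless profiles these refinements are
  no-ops (the profile is symmetric about the waist). Ties go to the station
  nearest the base. A profile whose minimum sits at the first station with
  monotonically increasing areas has no interior constriction and is flagged
  `non_constricted`.
* **Width W** = mean of the two side lengths of the minimum-area *rotated*
  bounding rectangle of the neck loop (rotating calipers on the convex hull,
  so tilted profiles are handled); **aspect ratio AR** = major/minor side.
* **Length L = L1 + L2**, where each L_i is the distance from the neck to the
  nearest *sampled* station whose area is at least 1.2-fold the neck area —
  L1 toward the NE, L2 toward the ER. No interpolation is used, so each side
  quantizes upward by at most one step (±0.5 nm at the default step). A side
  whose series ends before the threshold (junction cut by the tomogram
  border) is flagged `truncated_L1`/`truncated_L2` and L is undefined;
  flagged junctions are excluded from summary means.
* **Shrinkage correction.** Plastic embedding and beam exposure shrink the
  specimen by a fraction f (default 0.17); native = measured / (1 − f).
  Linear, so it applies to widths, lengths and sums alike.
* **Auxiliaries.** Sagittal side profiles (plane slice through the axis,
  split left/right); 2-point widths (Euclidean distance, for lower-resolution
  FIB-SEM-style measurements); perinuclear-space width below a junction
  (base point to nearest inner-nuclear-membrane point, with two flanking
  controls 200–500 nm away); point-to-surface distances (vectorized exact
  point–triangle projection; no spatial index required).

Annotations labelled `contact_site` (membranes apposed but not continuous)
are counted in abundance tallies but barred from neck morphometry.

## Abundance and stereology

Junction frequency = deduplicated junction count / screened NE area. The NE
area comes from either (a) stitching traced NE contours into a mesh and
summing triangle areas, or (b) Σ lengthᵢ × depthᵢ over near-flat regions;
on synthetic near-flat envelopes the two agree within 3 %, cross-validating
each other. Frequencies are kept unrounded internally; reports carry both
the two-decimal rounded value and the two-decimal truncation (21/112 =
0.1875 prints as 0.19 rounded, 0.18 truncated — both are emitted so either
printing convention is auditable). Per-nucleus totals multiply a frequency
by the total NE surface of an average nucleus (400 μm² early telophase,
800 μm² interphase, taken as constants) and are reported unrounded and to
one significant figure. Records closer than 50 nm across overlapping
volumes are merged (idempotent; the threshold is plumbing, chosen well below
any plausible junction spacing). Group width comparisons use the two-sided
Mann–Whitney U test (`scipy.stats.mannwhitneyu`).

Stereological screening of whole-nucleus masks: surface voxels are
foreground voxels with a six-connected background neighbour (border voxels
do not count as surface — outside the array is unknown, not background);
n points (typically 52–56) are spread over the surface by a seeded random
first point followed by farthest-point sampling, a reproducible
operationalization of "uniform radial" placement; spherical ROIs (radius
800–1000 nm) crop subvolumes by voxel-centre distance in nm, so anisotropic
voxels (e.g. 4.0 × 4.0 × 3.4 nm FIB-SEM) are handled exactly.

## Synthetic geometries

All validation runs on generated surfaces with closed-form ground truth:

* **Hourglass (ER–NE) junctions**: a hyperboloid of revolution,
  r(s) = r₀√(1 + s²/c²), optionally squeezed into an elliptical section
  (major/minor = ellipticity), merged into a flat NE annulus at the base and
  open at the ER side. Cross-section area is A(s) = A(0)(1 + s²/c²), so the
  1.2-fold-area length is exactly 2c√0.2, the true width is
  neck_diameter·(1 + ellipticity)/2 and the true AR is the ellipticity.
  Defaults: neck diameter 17.4 nm and population s.d. 5.0 nm for with-lumen
  junctions, 6.9 ± 1.1 nm for no-lumen junctions (profiles trace the bilayer
  midline, so a no-lumen neck is about one bilayer thick); neck scale
  c = 11.6 nm, giving a default neck length 2·11.6·√0.2 ≈ 10.4 nm; flare
  length 15 nm, placing the neck inside the 25 nm search window.
* **Wide-cone (ER–ER) junctions**: a monotonically widening funnel
  r(s) = r_base(1 + s/c) with no interior minimum; the true width is the
  base opening.
* **Tracing jitter** emulates manual segmentation error: i.i.d. isotropic
  Gaussian offsets (s.d. = jitter_sd per component) drawn on a coarse
  control grid with ~3 nm axial spacing and 8 angular nodes — the scale of
  the traced slices, not the sub-nm tessellation pitch — interpolated
  bilinearly to the vertices and tapered to zero at the open tube ends so
  the mouth stays planar. Per-vertex independent noise was rejected: at a
  0.5 nm tessellation pitch it destroys the surface topology (plane sections
  stop being closed loops), which no tracing error does. A consequence worth
  knowing: correlated noise *physically* narrows the minimal neck of the
  generated surface (by ≈ 0.25 nm at jitter 0.5 nm); a 0.1 nm fine-scan
  oracle confirms the pipeline tracks the actual jittered geometry to
  ~0.02 nm.
* **NE sheets** as open-contour stacks (straight or circular-arc traces,
  area = arc length × depth); **nuclei** as solid ellipsoidal voxel masks
  with seeded sub-voxel centre jitter so the discretization is not
  grid-aligned.
* **Populations**: n junction meshes with neck diameters drawn per lumen
  class from normals truncated at 2 nm, placed uniformly on a square sheet
  of the requested area; every scene is a pure function of its spec and
  seed.

What the synthetic model does *not* emulate: image formation (missing wedge,
noise), membrane biophysics, non-axisymmetric necks beyond ellipticity, and
junction clustering. Passing tests therefore demonstrate the correctness of
the geometry pipeline under a realistic noise model, not the biological
width values themselves, which require real tomograms and their
segmentations.

## Numerical choices and degenerate inputs

* Contour stitching uses the shortest-diagonal zipper between consecutive
  resampled, start-aligned contours. A per-triangle minimal-area greedy was
  rejected: with unequal point spacing it exhausts the finer contour first
  and grossly inflates the band area; the shortest-diagonal rule keeps the
  fronts in lockstep and is near-minimal for overlapping contours.
* Section planes advance by 10⁻⁶ nm along the axis so stations never land
  exactly on a vertex ring.
* `min_area_rect` rejects collinear loops; polygon area is the shoelace
  magnitude (orientation-independent); loop selection at a station takes the
  closed loop with the nearest centroid, ties broken toward smaller area.
* Degenerate inputs raise: single-point contours, non-overlapping
  consecutive contours, zero-depth sheets, semi-axes below one voxel,
  all-foreground masks, coincident 2-point measurements, factor ≤ 1,
  shrinkage fraction outside [0, 1), more sample points than surface voxels.
* Problem sizes in the test-suite and acceptance runs: tessellation pitch
  0.5 nm (≈ 60 axial rings, 48–256 angular segments), 100-junction
  recovery populations, 1 μm-radius nuclei at 50 nm voxels. These keep a
  full run in the low minutes while leaving tessellation error an order of
  magnitude below the measurement tolerances.

## Known limitations

* The adaptive centreline assumes the junction axis never bends more than
  15° per step and that sections stay simply connected; pathological
  branched necks are out of scope.
* L is quantized to the section step (no sub-step interpolation), matching
  the nearest-sampled-station definition; at Δs = 0.5 nm this bounds the
  discretization error at +0.5 nm per side.
* Whether the 25 nm neck-search window is measured along the centreline arc
  or the straight axis is a convention; arc length is used here (the two
  coincide for straight fixtures).
* The stereology report treats findings as externally supplied (manual or
  automated screening); it does not detect junctions in image data.
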