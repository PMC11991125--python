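# Methods

This note records the models, conventions, numerical choices, and
limitations behind `sonoloft`.  Units are millimetres, mm², mm³, and
degrees (counter-clockwise positive) throughout every interface.

## Coordinate conventions

* **Image frame.**  Pixel data are row-major, y-down.  On contour
  creation, pixel coordinates are converted to millimetres with the slice's
  own pixel spacing and the y-axis flipped upward, so the image's lower-left
  corner is the origin and rotations follow the mathematical convention.
  Mixed pixel spacings across views are allowed.
* **Base frame.**  The probe view at 26° is the reference; every other
  view is placed by a single rigid pose `p ↦ R(θ) p + a`, where `a` (the
  "anchor") is the base-frame position of the image's characteristic
  corner.  Poses are normalized to θ ∈ (−180°, 180°].
* **Scan axis.**  Step 0 is the proximal base plane; stepping proceeds
  along negative Z (`z_k = −k·step`), so centers of gravity of distal
  structures have negative Z.  The trajectory log records the robot's
  displacement magnitude (positive).
* **Contours** are dense closed polylines, stored counter-clockwise.
  Consecutive duplicate vertices are removed on ingest; remaining
  self-intersections raise an error rather than being repaired silently
  (the only exception is the B-mode tracer's own pixel-level output, which
  may be repaired before a contour is built, since the artifact is created
  by the tracer itself).

## Geometry primitives

Area is the shoelace signed area; the section centroid is the enclosed
lamina's centroid (Green's-theorem form), not the vertex mean.  Contours
are resampled by equal arc length, starting at the first vertex.  Inside
the lofter only, when the target ring count is at least twice the input
vertex count, the sample nearest each original vertex is snapped onto it:
polygonal sections (rectangles) then keep their corners exactly, which
makes prism volumes exact instead of accurate to a corner-cutting term.
The standalone resampling operation keeps plain equal spacing.

## Registration

The manual image alignment this package automates has no published
objective, so RMS contour distance is assumed.  `register_slice_pair`
minimizes the RMS point-to-nearest-segment distance from the (resampled)
moving contour to the fixed contour polyline:

* **Initialization** — centroid-difference translation plus a coarse
  rotation grid (15° spacing, capped at ±90°).  The cap encodes that probe
  angular offsets are physically small; it also removes the 180°-flip
  ambiguity of nearly elliptical cross-sections, whose branch choice would
  otherwise be decided by noise and could corrupt pose averaging across
  calibration sections.  Near-ties (within 10% residual) break toward the
  smallest rotation magnitude for the same reason.
* **Refinement** — point-to-line Gauss–Newton ICP: each iteration solves
  the linearized normal-projected least-squares problem for (dθ, dt).
  Point-to-point projection ICP converges only linearly here (tangential
  sliding); the normal formulation converges in a handful of iterations.
  Correspondences beyond 3× the median distance are rejected.
  Near the noise floor the correspondence set can limit-cycle, so the loop
  keeps the best transform seen and stops when the best RMS has not
  improved by more than `1e-6 mm + 1e-4·rms` for five consecutive
  iterations; hitting the iteration cap (100) without stalling raises a
  non-convergence error carrying the last residual.
* **Averaging** — one pose per view is estimated from five non-adjacent,
  evenly spaced calibration sections (configurable) in which the shared
  structure has at least 25 mm² of area in both views: anchors are
  arithmetic means, angles circular (resultant-vector) means.
* Scaling is never estimated; slice images are assumed pre-scaled to mm.
* Probe angles (354/26/45°) are acquisition labels only; registration
  angles are independent quantities and never derived from them.

## Fusion, stacking, lofting

Each structure is taken only from the view where it appears entire
(configured assignment); duplicates from other views exist solely to drive
registration.  A stack starts at the first step where the structure is
present and ends at the first absence — no interpolation across gaps —
with a cross-sectional-area cutoff of 1 mm² (roughly the resolution limit
of the emulated scanner) treating vanishing sections as absent.

Lofting resamples every section to `n_ring = 128` boundary points, aligns
consecutive rings by the cyclic offset minimizing summed squared vertex
distance (ties to the smallest offset, for determinism), stitches
2·n_ring triangles per band, and caps the end sections with centroid
fans.  Winding is fixed globally by the sign of the enclosed volume.  The
mesh is audited edge-manifold (every undirected edge in exactly two
faces, once per direction) before any volume is reported.

Volume and center of gravity use signed-tetrahedron (divergence-theorem)
integration against the origin; volume is rigid-invariant and the COG
rigid-equivariant to floating-point precision.  Group aggregates are the
plain sum of member volumes and the volume-weighted mean of member COGs —
not a re-loft of a merged outline — so group totals are exactly additive.

Expected discretization behaviour: a 128-gon inscribed in a smooth
section under-measures area by ≈ 4×10⁻⁴ relative; linear ring-to-ring
interpolation under-measures a concave taper by O(step²).  At a 5 mm step
over a 200 mm spindle the combined volume error is ≈ 0.2%, and it
decreases monotonically under step refinement (verified in the tests).

## Phantoms and the scan simulator

The synthetic module defines the study conditions:

* **Scan protocol**: 5 mm step, 44 steps, probe views 354/26/45° with 26°
  as base; positioning noise σ = 0.1 mm (the robot's stated accuracy);
  probe force logged as 5 N ± 0.2 N (the force sensor's accuracy, well
  inside its 50 N range).  Probe pressure does not deform the phantom —
  the physical setup uses a thick gel cushion precisely to level out
  deformation — so force is metadata only.
* **Layered slab**: plates of 85 mm width mimicking skin (1.5 mm,
  hyperechoic), subcutaneous fat (7 mm, mid-level speckle), and muscle
  (15 mm, hypoechoic with a 2 px hyperechoic fascia-like rim drawn just
  inside the outline), stacked 1.5 mm apart (the physical arrangement is
  1–2 mm; touching layers are rejected), 30 mm long.  The mold dimensions
  of the physical phantom being emulated are not published, so these are
  self-declared synthetic values at the physically stated scale.
* **Muscle spindle**: elliptical cross-sections with piecewise-polynomial
  semi-axis profiles; default a 200 mm spindle with quadratic profiles
  vanishing at the ends and peaking at 15 × 10 mm — forearm-extensor
  scale.  Volume π∫a·b dz and COG are integrated exactly per polynomial
  piece (products of pieces are polynomials; antiderivatives are
  evaluated in exact arithmetic up to floating point).  Distinct semi-axes
  keep in-plane rotation observable to the registration stage.
* **Rendering**: class mean intensities 210 / 120 / 55 / 5 (hyperechoic /
  mid / hypoechoic / anechoic) on 8-bit pixels at 0.2 mm/px, multiplied by
  partially developed speckle `1 − w + w·R` with `R` unit-mean Rayleigh
  and contrast `w = 0.6` (fully developed speckle at the brightest level
  would clip heavily at 255 and blur the class separation that the
  physical phantom was designed to exhibit).  The skin plate renders at
  gain 0.62 by default — its physical counterpart was poorly visible —
  with a boost flag used whenever skin is to be segmented.
* All randomness flows from one seed through `SeedSequence` spawn keys
  (per view, step, and purpose), so records and logs are reproducible and
  independent of evaluation order.

## B-mode segmentation defaults

Extraction is Gaussian speckle smoothing (σ = 1.5 px) → per-class
intensity bands placed at the midpoints between rendered class levels
(hyperechoic floor lowered to 150 for the clipping-induced mean shift) →
morphological opening/closing (radius 3 px; 2 px for the hyperechoic
class so thin bright plates survive while 2 px rims do not) → hole
filling → 8-connected components → minimum-area rejection (5 mm²) →
marching-squares boundary tracing → polygon simplification (0.75 px).

Thresholding a blurred edge lands the traced boundary slightly inside the
true one, and bordered structures additionally lose their internal rim;
the traced polygon is therefore offset outward (`grow_mm`): 0.5 mm for
bordered structures (2 px rim + threshold shift) and 0.15–0.2 mm
otherwise.  These constants follow from the renderer's geometry at
0.2 mm/px and were fixed by measuring the uncompensated bias of straight
slab edges; with them, layer areas are recovered within ~1% and Dice
≥ 0.99.  In the pipeline, traced contours are densified to 256 points
before the 5-point circular smoothing — averaging a sparse polygon would
shrink convex boundaries measurably.

What passing synthetic tests do **not** show: performance on clinical
ultrasound.  The renderer has no attenuation, shadowing, refraction, or
beam-width effects, and the intensity bands are matched to the renderer;
the extraction is a verification tool for the geometry pipeline, not a
clinical segmenter.  Boundary placement in low-contrast tissue is
expert-dependent and has no algorithmic analogue here.

## Problem sizes used in tests and the acceptance script

Desk-scale throughout, chosen so the full suite runs in well under a
minute of computation per stage: 1000 random polygons for the area
oracle, 10⁶ rejection samples for the Monte-Carlo centroid check, 50
seeded trials for noisy pose recovery, the full 3-view 44-step scan for
the end-to-end runs (with B-mode rendering at 500×550 px), and a 1 mm
step for the slab verification.

## Known limitations

* In-plane (2D) rigid registration only; out-of-plane probe tilt is not
  modeled or corrected.
* No interpolation across missing sections (a flagged absence terminates
  the stack); structures must be simply connected per slice (outer
  boundaries only, no holes), mirroring the treatment of merged muscles
  as a single outer outline.
* Fascia-resolved splitting of merged structures is out of scope.
* Lofting assumes ring-to-ring correspondence by cyclic offset; strongly
  twisted or branching anatomy would need correspondence by feature
  matching, which is not implemented.
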