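# Methods

## Problem and pipeline overview

The measurement target is the spatial attitude of the six semicircular
canals: an oriented unit normal per canal plane, expressed in a
reproducible head-internal coordinate system, plus derived angles.
Input is a labeled volume (left/right canal masks, two eyeballs) in the
fixed anatomical axis convention *x* left→right, *y* posterior→anterior,
*z* inferior→superior; NIfTI volumes are re-oriented to this convention
(RAS+) on load from their affine, so scanner orientation is irrelevant.

Stages, in order:

1. **Mask conditioning.** The combined canal mask is smoothed by a 3×3×3
   majority vote. This removes salt-and-pepper segmentation errors
   without moving the tube centerline; on noise-free input it is a
   near-no-op.
2. **Side split and thinning.** The mask is split at its center of mass
   along *x* into left and right halves; each half is reduced to a
   one-voxel-wide centerline by connectivity-preserving 3D thinning
   (scikit-image). Thinning runs in index space because the downstream
   adjacency threshold is stated in index units; physical (mm)
   coordinates are attached afterwards and used for all geometry.
   The right side is thinned in mirrored orientation and flipped back:
   parallel 3D thinning is not mirror-symmetric (its directional
   sub-iterations impose a chirality), and canonicalizing the chirality
   makes the whole measurement exactly equivariant under left–right
   reflection — verified to 0.0000° on mirrored phantom pairs. Without
   it, thinning asymmetry alone contributed up to ~1.7°.
3. **Point classification and cleaning.** Skeleton points become nodes
   of an adjacency graph: two points are adjacent iff the Euclidean
   distance of their voxel indices is strictly below 2. Since
   26-neighbour distances are at most √3 ≈ 1.732, this threshold
   reproduces 26-connectivity while excluding next-nearest voxels at
   distance 2. Nodes are classified by degree: crossing (>2), ordinary
   (=2), terminal (=1), discrete (=0). Connected components smaller
   than 10 points and terminal branches of ≤6 points ending at a
   junction are removed iteratively; genuine canal branches are an
   order of magnitude longer, while surface bumps under boundary noise
   generate exactly such spurs.
4. **Canal identification and tracing.** Per side, three poles are
   found: the most superior point (anterior canal), the most posterior
   (posterior canal) and the most lateral (lateral canal); ties break
   by distance from the side centroid, then lexicographic index order.
   From each pole the centerline is traced in both directions through
   ordinary points until a crossing or terminal point ends the walk
   (endpoints included). The highest crossing point of a side is taken
   as the top of that side's common crus — the superior junction where
   the anterior and posterior canals merge.
5. **Standard frame.** The initial lateral plane passes through both
   crus tops and the lowest (minimum-*z*) eyeball voxel, eyeballs
   pooled. It is refined to a *supporting* plane: iteratively select
   the eyeball voxel with the greatest signed distance below the
   current plane and rebuild the plane through it and the crus tops,
   until the selected point is stable (≤20 iterations; convergence is
   verified against an exhaustive supporting-plane oracle). Axes:
   X = plane normal, superior-positive; Z = the crus-top line projected
   orthogonal to X (the line is generally not exactly orthogonal to the
   plane normal), rightward-positive; Y = X×Z, anterior-positive.
   With these stated sign conventions the triad is left-handed
   (det = −1); the handedness is recorded in the frame metadata. The
   alternative Y = Z×X would point posterior under this axis
   convention, contradicting the stated anterior-positive direction, so
   the stated signs win.
6. **Trimming.** Each traced path is fitted with an open cubic B-spline
   p(u) = Σ Pᵢ B_{i,k}(u) (scipy `splprep`), smoothing factor
   s = number of points (squared-mm residual budget) to suppress voxel
   quantization in the derivatives; s = 0 reproduces exact
   interpolation. Curvature κ = ‖r′×r″‖/‖r′‖³ and torsion
   τ = (r′×r″)·r‴/‖r′×r″‖² are evaluated at 200 uniform parameters
   (where ‖r′×r″‖² < 1e−12 the torsion is set to 0 and the sample
   flagged straight). Each series is standardized separately; samples
   with |z| > 2 SD in either series are anomalous. The first/last 2 %
   of the parameter range are excluded from the mean/SD estimates
   (spline end effects would otherwise dominate the SD) but still
   receive flags. A series whose SD is below 1e−3 mm⁻¹ is treated as
   constant and contributes no flags: the torsion of a planar
   centerline is pure floating-point noise (~1e−5 mm⁻¹), two orders of
   magnitude below real canal curvature/torsion variation, and
   z-scoring it would flag arbitrary samples. Path points whose
   nearest spline sample is flagged are removed; the longest contiguous
   surviving run is kept (plane fitting needs a contiguous arc). If
   fewer than 60 % of points survive the canal is marked over-trimmed
   and reported for manual review instead of being silently fitted.
7. **Plane fit and orientation.** The canal normal is the
   total-least-squares plane normal of the trimmed points: centre the
   points, SVD of the centred matrix, normal = right-singular direction
   of the smallest singular value; RMS point–plane distance =
   σ_min/√n. SVD normals are sign-ambiguous, so normals are
   canonicalized in the standard frame: lateral canals point inferiorly
   (X-component < 0, fallback Y < 0), anterior/posterior canals point
   posteriorly (Y < 0, fallback X > 0) — the hemispheres in which the
   published cohort means lie. Direction angles are the arccosines of
   the oriented normal's components.
8. **Cohort aggregation.** Mean normal per canal V̄ = Σvᵢ/‖Σvᵢ‖ over
   subjects; deviation = mean and population SD of the angle of each
   subject's normal to V̄; dihedral angles between canal planes
   reported both as the mean of per-subject dihedral angles and as the
   angle between cohort mean normals — the two estimators differ once
   normals vary across subjects, and published cohort dihedral tables
   are consistent with the per-subject average rather than with angles
   between the printed mean vectors.

### Windowed versus global plane fit

A point-by-point mode is available (`fit_mode="windowed"`): sliding
windows of ⅓ of the trimmed path (stride 1), one sign-aligned SVD
normal per window, subject normal = V̄ over windows. On analytic arcs
the two modes agree; on voxelized centerlines the short windows amplify
quantization wobble into a correlated bias (phantom benchmark across 6
seeds: windowed max error 2.8°, mean 1.0°, versus global max 1.1°,
mean 0.4°, worst for the near-horizontal lateral canal, for any window
fraction between ⅓ and 0.8). The global trimmed fit is therefore the
default subject-level estimator.

## The synthetic phantom

Each side consists of three planar circular arcs swept into tubes
(anterior and posterior: arc radius 7.5 mm; lateral: 6.5 mm; duct
radius 1.5 mm; span 300°), an ampulla bulge (radius 2.2 mm) at each
arc's free end, and a common-crus tube (radius 1.5 mm) whose top is the
junction of the anterior and posterior arcs and which continues 10 mm
below the lateral-canal junction. Eyeballs are spheres (radius 11 mm)
placed anterior-inferior at adult interocular spacing. The grid is
201×221×141 voxels at 0.5 mm isotropic spacing; dimensions are a
modestly enlarged human labyrinth so the ducts are ~3 voxels in radius
and survive thinning cleanly. Two rasterization details matter:
the below-junction crus stub is kinked slightly off-vertical, because
parallel 3D thinning deletes perfectly axis-aligned even-width tubes
outright (a 6-voxel-wide box thins to zero voxels) and retracts blunt
dead ends by several voxels; and canal arcs depart their junction in
well-separated directions so the skeleton junction stays within ~2
voxels of the true crus top.

Canal-plane orientations default to published adult cohort means,
specified in the standard frame and mapped into image space through the
frame of the base landmarks; each side then receives an independent
small rigid jitter (rotation σ = 1°, translation σ = 0.25 mm), so left
and right are realistically imperfect mirror images and different seeds
emulate different subjects. Because every canal is a *planar* arc, the
true normals are exact, making the phantom a ground-truth oracle for
the full pipeline. `mirror_spec` reflects a phantom across the
mid-sagittal plane (an exact voxel flip of the rasterized volume),
supporting bilateral-symmetry checks.

Boundary noise flips voxels within one voxel of a structure surface
independently with probability p (default condition p = 0.05),
emulating segmentation error without destroying topology.

What the phantom does **not** emulate: non-planar (twisted) canal
courses — real anterior canals in particular are measurably twisted, so
real-data normals depend more on the trimming range than phantom
results suggest; MRI intensity, partial-volume and resampling effects;
anisotropic clinical voxels (supported by the code, not exercised by
the default phantom); and anatomical variation beyond small rigid
jitter. Passing recovery tests therefore demonstrates correctness of
the geometry pipeline, not segmentation robustness on clinical scans.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| adjacency threshold | 2 (strict <) | voxel index | reproduces 26-connectivity; √3 < 2 ≤ next-nearest |
| spline order k | 3 | – | cubic: C² continuity for κ and τ |
| smoothing s | n points | mm² | ~1 voxel² residual per point; 0 = interpolate |
| profile samples m | 200 | – | resolves flags at sub-point granularity |
| z-score cutoff | 2 | SD | standard outlier criterion |
| SD floor | 1e−3 | mm⁻¹ | below measurable κ/τ variation; guards planar inputs |
| min kept fraction | 60 % | – | less ⇒ over-trimmed error, manual review |
| spur length / component size | 6 / 10 | points | an order below genuine branch lengths |
| window fraction (windowed mode) | ⅓ | – | ≥ 120° of arc per local fit |

## Numerical choices and degenerate inputs

Ties in pole finding and lowest-voxel selection break deterministically
(distance from centroid, then lexicographic index; smallest *x*, then
most posterior). Dice of two empty masks is an error, not 1.0 — the
metric is undefined and silence would hide upstream failure. Collinear
landmark triples, unilateral inputs, missing junctions, antipodal
normal sets and poles on non-ordinary points all raise descriptive
errors; inside the subject pipeline such failures become per-canal QC
flags and only a failed reference frame aborts the subject. All
randomness lives in the phantom generator (a single seed); the
measurement path is fully deterministic, and re-running a measurement
reproduces byte-identical JSON output.

## Verification problem sizes

The test suite and acceptance script run phantom pipelines at the
default grid (6.3 M voxels, ~1 s per subject end-to-end): recovery on
noise-free phantoms (normals within 2° of truth, canal identity exact),
five boundary-noise seeds at p = 0.05 (within 5°), exact mirror
equivariance (<0.5°, measured 0.0°), closed-form curvature/torsion on
circle and helix (rel. error < 1e−3), SVD fits against an
eigendecomposition oracle (< 1e−9 rad), and fundus refinement against
an exhaustive supporting-plane search (< 1e−6 mm). Cohort statistics
in the acceptance script use five phantom subjects.

## Known limitations

- The common-crus top is operationalized as the highest skeleton
  crossing point; on real data with segmentation defects near the crus
  this landmark inherits skeleton errors directly, and a ~1 voxel bias
  in both crus tops tilts the frame by ~1°.
- The 2 SD trimming rule assumes the anomalous (ampullar) section is a
  minority of the path; canals whose masks include long vestibular
  extensions may hit the over-trimmed guard and need manual range
  selection.
- Only plane attitude is measured; within-canal torsion profiles are
  computed but not summarized (no surface/segment-wise analysis).
- Cohort deviation statistics on phantoms reflect the generator's 1°
  jitter, not biological variation; they validate bookkeeping, not the
  published spread values.
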