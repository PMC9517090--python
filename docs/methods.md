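# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `maxalign`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is quoted from
external measurements.

## Problem setting

Orthognathic surgery repositions the maxilla according to a virtual
surgical plan (T0, an STL surface exported from planning software). The
achieved result is a postoperative CBCT-derived surface (T1). Accuracy is
the deviation of achieved from planned, measured without anatomical
landmarks: the two surfaces are rigidly registered on a cranial region
surgery does not alter, and the residual misfit of the maxillary region is
the error. The single-number accuracy metric is the RMS of the per-point
point-to-surface distances over the maxillary region ("3D error"), with a
clinical acceptability band of ±2 mm.

## Mesh handling (mesh_io)

- STL carries no units; all coordinates are interpreted as **millimetres**
  (the CBCT export convention).
- Binary/ASCII dialects are auto-detected (declared record count vs file
  size first, then the `solid` header). Parse errors name the byte offset
  (binary) or line number (ASCII) of the first bad record. Attribute bytes
  are ignored on read and zeroed on write.
- STL stores each triangle's vertices independently; on read, vertices
  within **1e-6 mm** are merged so faces share indices. This tolerance is
  far below CBCT voxel size (~0.3 mm), so no distinct anatomy can merge,
  while exact per-facet duplicates always do.
- `validate_mesh` removes faces with repeated vertex indices or area below
  `area_epsilon` (default 1e-12 mm²) and then unreferenced vertices; it is
  idempotent. Normal computation refuses degenerate faces and directs the
  caller to validation.
- Face winding is trusted as read; there is no global re-orientation pass.
  Signed deviation therefore *checks* winding consistency (no interior edge
  traversed twice in the same direction) and refuses inconsistent inputs
  rather than silently producing mixed signs.
- Binary STL stores float32 coordinates: a write/read round trip is exact
  only to ~1e-5 mm at 100 mm coordinate magnitude. ASCII output is written
  with 17 significant digits and round-trips exactly. This matters only
  when chaining sub-micrometre checks through files; it is far below every
  clinical tolerance.

## Regions of interest (roi)

Hand-painted ROI selection is replaced by explicit vertex-index lists or
closed geometric predicates (axis-aligned box, sphere, half-space), stored
as small JSON documents, so selections are exactly reproducible. Membership
is vertex-based; a face belongs to an ROI sub-mesh only when all three of
its vertices are selected — conservative, and it never invents boundary
geometry. Operator-to-operator variability of a hand-drawn boundary is
emulated by seeded random removal of a small fraction of ROI vertices.

## Registration (registration)

- **Rigid fit**: weighted least squares via SVD of the cross-covariance
  (Kabsch). The reflection case is resolved by sign-flipping the smallest
  singular vector so det = +1. Near-collinear configurations (second
  singular value ≤ 1e-12 of the first) are rejected.
- **Initial alignment**: centroid + principal axes (descending eigenvalue
  order); among the four proper-rotation sign assignments the one with the
  smallest nearest-neighbor RMS wins. If any adjacent eigenvalue pair is
  within a factor 1.05 the axes are unreliable and the method falls back to
  centroid-only alignment with a warning.
- **ICP variant**: point-to-*mesh* — correspondences are exact closest
  points on the target triangles, not nearest vertices — which makes the
  result insensitive to how differently T0 and T1 are tessellated. The
  per-step metric is classic point-to-point least squares on the current
  closest-surface-point pairs; point-to-plane is out of scope.
- **Exact accelerated queries**: a k-d tree over triangle centroids bounds
  the candidate set per query (distance to the seed face + the largest
  centroid-to-corner radius); every candidate is then tested with the exact
  point-to-triangle projection. Results equal an exhaustive all-triangles
  scan bitwise (ties broken toward the lowest face index, so runs are
  reproducible).
- **Trimming**: each iteration keeps the best `1 - trim_fraction` of pairs
  (default 0.1) and optionally gates on `max_correspondence_distance`
  (default unbounded). Trimming guards the reference-region fit against
  plate/metal rendering artifacts that survive segmentation.
- **Convergence**: stop when the survivor RMS changes by less than
  `rms_change_tolerance` (default 1e-5 mm) or after `max_iterations`
  (default 100). The survivor RMS is non-increasing after the first
  re-correspondence: re-correspondence can only shorten each point's
  distance, the trimmed subset has fixed size, and the Kabsch step
  minimizes the squared sum.
- The defaults assume ICP starts from the principal-axes initial alignment,
  as the pipeline always does; there they converge in a handful of
  iterations. Started from an *identity* initialization on a smooth shell,
  ICP slides tangentially with slow linear convergence and can exhaust the
  default budget far from the optimum — callers using `icp_refine` directly
  with a crude initialization should raise `max_iterations` and tighten
  `rms_change_tolerance` (the unit tests do).
- Direction: T1 is registered onto T0 — T0, the plan, is the fixed
  reference frame — and the resulting transform is applied to the whole T1
  mesh before deviation analysis.

## Deviation (deviation)

- Sample points are the registered T1 ROI2 vertices; the reference is the
  T0 ROI2 sub-mesh (achieved vs planned; the reverse direction is behind a
  flag). This is one-directional, not a symmetric Hausdorff measure.
- The 3D error (RMS) is computed on **unsigned** distances: it is a
  magnitude-of-error measure and the ±2 mm band is symmetric. The signed
  field (sign from the reference face normal at the closest point; zero
  distance counts positive) exists for the colormap and min/max reporting.
- The acceptability band is **closed**: RMS = 2.0 mm is acceptable. The
  comparison uses an absolute 1e-9 guard so a computed RMS that equals the
  threshold up to last-ulp rounding is not misclassified.
- Colormap: linear blue (−range) → green (0) → red (+range), clamped
  beyond; range defaults to the 2 mm threshold.

## Statistics (stats)

- Per-case value = arithmetic mean of operator replicates.
- Group summaries use the sample SD (n−1); with n = 1 the SD is undefined
  and flagged.
- The group contrast defaults to the independent-samples pooled t-test
  (t = Δmean / (s_p·√(1/n_a+1/n_b)), df = n_a+n_b−2, two-tailed). A paired
  test between arms containing *different patients* is undefined, so paired
  mode exists only for genuinely coupled designs; Welch mode is available
  when variances differ. Significance level α = 0.05, configurable.
- Normality: one-sample KS against a normal with the sample's own mean and
  SD, with Lilliefors small-sample corrected p-values (stricter than the
  naive KS table when parameters are estimated). Implemented via
  statsmodels.
- Zero-variance degenerate inputs with equal means yield t = 0, p = 1 by
  convention.

## Synthetic phantoms (synthetic)

What the generator emulates: a rigid cranial reference shared between T0
and T1 up to a global pose change (different scan frames), a maxillary
region displaced by a known rigid residual (the surgical inaccuracy),
isotropic Gaussian vertex noise (surface-reconstruction error; optionally
along normals), and large outlier displacements of 2–5 mm along normals on
a fraction of maxillary vertices (plate/metal artifacts).

Geometry is schematic: a half-ellipsoid cranial shell (default radii
80×68×60 mm) and a detached maxillary ellipsoid (25×18×12 mm). The shell
carries a deterministic low-order asymmetric radial modulation (default
amplitude 0.12) emulating the front-biased orbital/zygomatic prominences; a
perfectly symmetric dome would make reference-region registration
rotationally ambiguous, which real anatomy is not. Tessellation density is
a free parameter (defaults: 289 + 182 vertices) — exports from planning
tools do not prescribe one.

What the phantoms do **not** emulate: real anatomy, CBCT physics,
segmentation bias, multi-fragment (segmental) osteotomies — the segmental
subgroup exists as a label only, with a single rigid maxilla. Passing tests
therefore demonstrate correctness of the *measurement machinery* (registration,
distances, statistics) under the stated error model, not clinical validity
on patient data.

T0 and T1 share tessellation topology by default (the pipeline never
exploits this; a tangential-jitter flag emulates independent remeshing).
All randomness flows from the explicit seed; two calls with the same spec
are bitwise identical. The maxillary residual is applied as an increment
about the maxilla centroid so an identity residual reproduces T0 exactly.

**Cohort generator.** Per-case target 3D errors are drawn moment-matched:
the drawn targets in each group have sample mean exactly the requested
group effect and sample SD exactly the requested between-patient SD, so a
cohort's realized generating means never drift from the nominal effects by
sampling luck. Each case's residual is a translation along a random
direction whose magnitude is calibrated by 1-D root finding (Brent) so the
noiseless ground-truth ROI2 RMS equals the drawn target — translations are
used because their ground-truth RMS is cleanly calibratable; rotational
residuals remain available in `generate_phantom_pair`. Default effects are
1.22 and 1.63 mm with 0.4 mm between-patient SD and 0.05 mm surface noise —
plausible clinical magnitudes for the two transfer techniques — with pose
perturbations up to 10°/10 mm. Group labels: splintless vs splint;
subgroups alternate monobloc/segmental.

## Pipeline and problem sizes

Per case: load → validate → ROI selection → initial alignment (ROI1 points)
→ ICP (ROI1 points vs ROI1 sub-mesh) → transform whole T1 → ROI2 deviation
→ summary + acceptability; every stage logs key=value lines. Outputs per
case: summary table, per-point table, colormap PLY, log.

Validation workloads use deliberately small, fast problem sizes — phantom
meshes of a few hundred vertices, 20-phantom recovery sweeps, 2000 null and
500 alternative t-test simulations, a 10-case cohort — chosen so the whole
validation battery runs in well under a minute while keeping every check's
Monte-Carlo error comfortably inside its decision margin.

## Known limitations

- Rigid registration only; no scale (surgery preserves it), affine or
  non-rigid modes, and no point-to-plane or symmetric ICP variants.
- The error is a scalar magnitude field: it does not decompose into
  per-axis translations/rotations of the repositioned segment, and cannot
  say in which direction the plan was missed.
- Surface-based, not voxel-based, comparison.
- No mesh repair beyond degenerate-face removal; no DICOM ingestion or
  segmentation.
- Equivalence with proprietary inspection software can only be property-
  level (same formulas, same invariants), since its internal ICP settings
  are unpublished.
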