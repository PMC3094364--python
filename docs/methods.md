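# Methods

## Problem and data model

A study registers one daily MVCT (moving image) to the planning kVCT
(fixed/reference image) of the same patient. Images are axis-aligned 3D
scalar grids in Hounsfield units; voxel index `i` maps to the physical
point `origin + i·spacing` (mm), with no oblique direction cosines. Typical
geometries are 0.976×0.976×3.27 mm (kVCT) and 0.754×0.754×4–6 mm (MVCT);
the MVCT has a restricted axial field of view contained in the kVCT's.
MVCT intensities are assumed HU-calibrated: mutual information tolerates a
monotone intensity remapping, but the fixed −1000/−500 HU lung-segmentation
window does not, so uncalibrated MVCT input would corrupt the lung indices
even where the registration itself succeeds.

## Pre-processing

1. **Couch suppression.** Any above-threshold connected component whose
   centroid lies in the posterior 15% of the y-extent and is disjoint from
   the largest component is discarded before body selection.
2. **Body masking.** The body is the largest 3D connected component above
   −400 HU, hole-filled per axial slice; everything outside is set to
   −1000 HU so metric samples carry no information-free background.
3. **Axial cropping.** Reference slices whose centers fall outside the
   partner's physical z-extent (half-open interval) are removed, so that
   few metric samples map outside the MVCT domain.

## Transform model

`T(p) = R(p) + D(p)`: a 6-parameter Euler rigid motion (rotations composed
Z·Y·X about a fixed center) plus a cubic B-spline free-form deformation on
a regular lattice. The lattice covers the fixed-image domain with the
per-axis control spacing chosen as the largest value not exceeding the
request that divides the axis extent integrally, plus one margin control
point per side for the cubic support. All-zero coefficients give exactly
zero displacement; constant coefficients give exactly that constant
(partition of unity). Grid refinement between levels refits the coarse
field by sparse least squares on a dense sample grid (direct
normal-equation solve); dyadic halvings reproduce the field to round-off,
and smooth fields transfer to well under 0.05 mm.

## Similarity metric

Negative mutual information in the Parzen-window form: a zero-order (box)
window on the fixed-intensity axis, a cubic B-spline window on the moving
axis, 50 bins per axis by default (the customary choice for this metric;
configurable). The joint distribution is estimated from a seeded uniform
draw of body-voxel centers; moving intensities come from trilinear
interpolation, whose analytic spatial derivative closes the chain rule, so
the returned gradient is the exact derivative of the implemented objective
(verified against central finite differences to 1e-4 relative and against
a dense joint-histogram oracle to 1e-8). Samples whose transformed position
leaves the moving volume are dropped and the distribution renormalized; if
fewer than `min_samples` (default 1000, floored at 25% of the draw) remain,
the metric raises rather than optimize a collapsed distribution.

## Optimization schedules

**Rigid, 3 levels.** Image pyramid with shrink factors 4/2/1 per axis
(capped so no axis drops below 8 voxels) and matched Gaussian
pre-smoothing (sigma = shrink/2 voxels). Regular-step gradient descent over
the six parameters: step along −g/‖g‖ (initial 4 mm), halved on any
non-improving step, terminating when the step falls below the level's
minimum (1e-2, 5e-3, 2.5e-3) or after 200 iterations. Rotations are scaled
at 1 rad ≡ 50 mm so the six parameters are commensurate. Up to 30,000
samples (≤10% of body voxels) per level.

**Elastic, 4 levels.** Both images are blurred at full resolution with a
kernel that narrows per level — isotropic 16/8/2/0 voxels when the axial
voxel dimension is at least the in-plane one, otherwise 16/16/8, 8/8/4,
2/2/2, 0/0/0 ("dimension" read as voxel spacing); the sampling percentage
grows 0.8/3.4/9.3/19.7% with the per-level seed offset by the level index;
the lattice refines 96 → 64 → 45 → 30 mm (geometric interpolation between
the two published endpoints; after axial cropping an axis whose spacing is
already finer than the next request keeps it). Coefficients are optimized
by L-BFGS-B (memory 10, bounds ±60 mm, ftol 1e-13 so the projected-gradient
tolerance 1e-5…1e-8 governs, 500 iterations/level). Control points with
(near-)zero total basis weight over the sample set are frozen at their
current value: their objective direction is exactly flat and they would
otherwise drift. Consequently the field is only meaningful where data
constrain it — inside the body — and the null-stability guarantee
(self-registration displacement ≤ 0.5 voxel) is stated over body voxels;
in surrounding air the extrapolated field may be several mm even for
identical inputs.

Determinism: all sampling is seeded, both optimizers are deterministic, so
identical inputs and seed reproduce bitwise-identical transforms and
metrics.

## Validation suite

* **CC**: Pearson correlation over the overlap minus a 30-voxel x/y border
  and the first/last 2 z-planes (edges are interpolated from outside the
  volume and unreliable). Invariant under positive affine intensity
  rescaling.
* **TRE**: per-landmark Euclidean distance between `T(p_i)` and the
  reference position, with mean, sample (n−1) SD and max.
* **Lung segmentation**: per axial slice, connected regions of the
  [−1000, −500] HU window not reachable from the slice-border exterior air,
  intersected with the body mask and hole-filled (enclosed vessels belong
  to the lung); slices are piled into a binary volume. The window's lower
  bound carries a 0.5 HU guard so background fill (−1000 exactly) survives
  interpolation round-off. Left/right splitting takes the two largest 3D
  components, assigned by centroid x (patient left = larger x); a single
  fused component is split at the body's mid-sagittal plane.
* **Correspondence indices**: `V_E = 100 (V^CT − V^reg)/V^CT` (sign fixed
  by the published patient-1 worked example), centroid distance in mm, and
  Jaccard overlap, all computed on the axial sub-region imaged in both
  scans. That common extent is additionally trimmed by the same 2-plane z
  border as the CC: warped edge slices interpolate from outside the MVCT
  and otherwise lose whole slices of segmented lung to the fill value.
  When indices are computed on a *warped* MVCT, the body mask is
  re-extracted from the warped image itself — after deformation the
  patient outline no longer coincides with the reference body, and air
  pulled inside the reference outline must not masquerade as lung.
* **Wilcoxon signed-rank**: two-sided, zeros dropped, average ranks for
  ties; exact null distribution by dynamic programming over doubled ranks
  for n ≤ 25 (exact under ties as well), normal approximation with tie and
  continuity correction above. Cohort aggregation reports per-patient TRE
  summaries (means of session means), overall CC mean ± SD, and |V_E| and
  C_E means pooled over both lungs and all sessions; per-cell V_E keeps
  its sign, the cohort average uses absolute values.

## Synthetic phantom

The generator emulates a thorax kVCT: an elliptical body (soft tissue,
0 HU) containing two lung ellipsoids (−850 HU), a vertebral column
(+700 HU), a detached couch slab, band-limited texture and spherical
+300 HU landmark markers (radius 3 voxels) at catalogued anatomical sites
(carina, bronchial bifurcations, vertebral body, aortic arch, lung apices,
rib, breast-bone). Two realism constraints matter for testing:

* the chest wall is kept at least two in-plane voxels thick everywhere
  (checked by erosion at generation time) — a thinner wall breaks under
  warping/noise and opens the lungs to exterior air, which no real
  anatomy does;
* the texture is multi-scale (correlation lengths 1.5, 4 and 10 voxels,
  total SD = `texture_amplitude`, default 20 HU): real CT has structure at
  every scale, and without the coarse components the heavily blurred first
  registration levels see a featureless body and the metric surface goes
  flat.

Deformations are defined through the resampling (pull-back) map
`psi: deformed point → source point`, a sum of compactly supported
cosine-squared bumps tapered to zero at the image boundary, so the
deformed image is computed exactly and the Jacobian is checked for
foldover. The registration ground truth `T = psi⁻¹` is recovered by
fixed-point iteration (landmark self-consistency enforced to 1e-6 mm).
Modes: `mediastinal_shift` (lateral bump between the lungs),
`atelectasis` (radial contraction of one lung, with compressed parenchyma
densified toward fluid HU in proportion to the local Jacobian; the
contraction gain is calibrated by bisection so the final truth mask hits
the requested volume reduction, including partial-volume and
densification losses), `pleural_effusion` (basal fraction of one lung
replaced by +20 HU fluid plus an upward compression bump),
`body_shrink` (outward pull-back shell at the body surface plus mild
interior bumps — weight loss also drags interior anatomy; a pure surface
shell would leave the interior exactly rigid and make rigid-vs-elastic
comparisons ill-posed), and `smooth_random` (random bumps). Truth lung
masks are kept consistent with the HU model: a deformed-frame voxel
belongs to the truth mask only if it maps into the lung *and* its final
HU lies in the segmentation window.

MVCT degradation resamples to MVCT spacing (default 0.754×0.754×4 mm),
restricts the axial FOV, compresses contrast linearly about air (default
scale 0.9) and adds white Gaussian noise (default SD 30 HU) — chosen to
visibly degrade the metric without defeating the default schedules. It
does not model beam hardening, scatter, reconstruction artifacts or
respiratory motion; the phantom's tissues are piecewise-constant with
synthetic texture. Passing phantom tests therefore demonstrates correct
mechanics and recoverability of smooth deformations under noise and
resolution loss, not clinical-grade robustness to real MVCT artifacts.

Landmark "visibility" on real data is an expert judgment; here a landmark
is scored when its true deformed position lies inside the MVCT axial FOV
and its reference position inside the cropped registration domain,
yielding the realistic handful of visible markers per session.

## Stage-ordering checks

On every default scenario the suite asserts: elastic CC ≥ rigid CC,
elastic mean TRE ≤ rigid mean TRE, pooled two-lung mean Jaccard
elastic ≥ rigid, and for lateralized modes an improvement of the affected
lung's Jaccard and |V_E|. The *unaffected* lung's Jaccard sits at the
≈0.99 ceiling and may dip by <0.01 after the elastic stage, so the
ordering is stated per pooled mean and affected side, mirroring
cohort-level rather than cell-level claims.

## Problem sizes

The default phantom is 192×192×60 voxels at kVCT spacing and registers in
a few minutes on one core. Tests and the scenario suite run the same
schedules on 96×96×40 voxels at 2×2×3 mm (and 80×80×28 at 2.4×2.4×3.6 mm
for determinism checks), a package choice that keeps the full suite at
roughly two minutes; registration accuracy statements in the tests refer
to those sizes. On the coarsest (80³-scale) grids small-amplitude
deformations can see the elastic stage add ~1–3 mm of landmark error while
still improving global CC; the accuracy guarantees are therefore asserted
at the 96×96×40 scale.

## Known limitations

* No regularization or diffeomorphism guarantee: the FFD can in principle
  fold; the published parameterization relies on the multi-level schedule
  and coefficient bounds for plausibility.
* Landmarks are evaluated at analytic sphere centers; observer detection
  error is deliberately outside the test surface.
* Left/right assignment assumes patient orientation (left = larger x);
  images in other orientations must be reoriented first.
* The DICOM reader requires a single frame of reference, uniform slice
  spacing and identity direction cosines.
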