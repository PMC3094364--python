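# tomoreg

Elastic registration of daily megavoltage CT (MVCT) to the planning
kilovoltage CT (kVCT) for helical tomotherapy of lung cancer, with the full
validation toolkit used to judge whether the recovered deformation tracks
real anatomical change (atelectasis, pleural effusion, mediastinal shift,
weight loss) in the lungs.

During a course of thoracic radiotherapy the lung parenchyma can change
shape and volume substantially. Rigid setup registration cannot follow such
changes, so estimating the accumulated dose in lung requires a deformable
mapping between the planning kVCT and each day's lower-quality,
restricted-field-of-view MVCT. This package implements that mapping and the
machinery to quantify its accuracy — for physicists and image-analysis
researchers working with kVCT/MVCT pairs, and as a self-contained, fully
synthetic test bed when no patient data are at hand.

## Model

The spatial transform is a sum of a global rigid motion and a local
free-form deformation,

    T(p) = R(p) + D(p),        D(p) = Σ_ijk  c_ijk  β³(u−i) β³(v−j) β³(w−k),

where `R` is a 6-parameter Euler rigid transform, `D` a tensor-product cubic
B-spline displacement over a regular control-point lattice, and
`(u,v,w)` the point's lattice coordinates. Both stages minimize negative
mutual information in the Parzen-window (Mattes) form, estimated from a
random subset of body voxels:

* rigid: 3-level image pyramid (shrink 4/2/1), regular-step gradient
  descent with per-level minimum step lengths 1e-2 / 5e-3 / 2.5e-3;
* elastic: 4 levels over blur, sampling and grid spacing — Gaussian kernels
  16/8/2/0 voxels, sample percentages 0.8/3.4/9.3/19.7 % of body voxels,
  control spacing 96 → 64 → 45 → 30 mm, bounded L-BFGS-B with
  projected-gradient tolerance 1e-5 … 1e-8.

Validation: Pearson correlation coefficient over a border-trimmed overlap
(30 voxels in x/y, 2 planes in z), landmark target registration error
TRE_i = ‖T(p_i) − q_i‖ in mm, slice-wise region-growing lung segmentation
in the [−1000, −500] HU window, and per-lung correspondence indices —
percent volume error `V_E = 100 (V^CT − V^reg)/V^CT`, centroid distance
`C_E` (mm) and Jaccard overlap — restricted to the axial sub-region imaged
in both scans. Cohorts are summarized with exact Wilcoxon signed-rank
comparisons of rigid vs elastic indices.

A synthetic thorax phantom (HU-calibrated anatomy, high-contrast landmark
markers, analytically known smooth deformations for each anatomical-change
mode, MVCT-like degradation) provides ground truth for end-to-end tests.

## Worked example

Register a synthetic atelectasis case (left lung collapsed by 25%, MVCT
degraded to 0.754×0.754×4 mm with noise) and score it against ground truth:

```python
from tomoreg.pipeline import PhantomScenario, run_phantom_scenario
from tomoreg.phantom import PhantomSpec, DeformationSpec

scenario = PhantomScenario(
    "atelectasis",
    phantom=PhantomSpec(shape=(96, 96, 40), spacing=(2.0, 2.0, 3.0)),
    deformation=DeformationSpec(mode="atelectasis",
                                volume_change_percent=25.0,
                                side="left", seed=1),
    fov_z_mm=90.0)
report, result, truth = run_phantom_scenario(scenario, seed=1)
```

which prints, via the report fields:

```
ground-truth TRE (mm): rigid 2.57 -> elastic 0.96
CC:                    rigid 0.916 -> elastic 0.961
left-lung V_E (%):     rigid 24.05 -> elastic -1.46
left-lung JAC:         rigid 0.760 -> elastic 0.982
```

Rigid alignment alone leaves the collapsed lung 24% smaller than the
planning lung and landmarks 2.6 mm off; the elastic stage recovers the
landmarks to below the voxel size and the lung volume to within ~1.5%,
with the overlap rising from 0.76 to 0.98 — the qualitative signature of a
successful deformable registration of a collapsing lung.

The same pipeline runs on real data from the command line:

```sh
tomoreg register --fixed kvct.mha --moving mvct.mha \
    --landmarks kvct_marks.csv mvct_marks.csv --out results/ --seed 1
tomoreg phantom --scenario atelectasis --seed 1     # synthetic suite
tomoreg tables-check                                # reference-cohort arithmetic
```

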