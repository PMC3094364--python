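"""Study orchestration: pre-process -> rigid -> elastic -> validation metrics.

A *study* is one kVCT/MVCT pair.  The driver applies the pre-processing
steps (couch suppression, body masking, axial cropping of the reference to
the partner's z-extent), estimates the rigid and elastic transforms, warps
the MVCT onto the reference grid at both stages, and computes the full
metric suite (CC, TRE if landmarks are available, per-lung V_E / C_E /
Jaccard restricted to the common axial extent).  Cohorts of studies are
aggregated with rigid-vs-elastic Wilcoxon comparisons, and a phantom
scenario suite scores recovered transforms against synthetic ground truth.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__
from .errors import DegenerateInputError, TomoregError
from .image import (ImageVolume, Mask, PreprocessConfig, crop_axial_to_overlap,
                    extract_body_mask, mask_background, read_image)
from .metric import MIConfig
from .phantom import (DeformationSpec, PhantomSpec,
                      apply_synthetic_deformation, degrade_to_mvct,
                      generate_thorax_phantom, ground_truth_error)
from .registration import register_elastic, register_rigid, warp_moving_image
from .transforms import CompositeTransform, save_transform
from .validation import (LandmarkSet, SessionMetrics, aggregate_cohort,
                         correlation_coefficient, jaccard_index, lung_volume,
                         centroid_error, restrict_to_common_extent,
                         segment_lungs_region_growing, split_left_right,
                         target_registration_error, transform_landmarks,
                         volume_error)


@dataclass
class StudyConfig:
    """Configuration of one registration study (paths or in-memory images)."""

    fixed_path: str | None = None
    moving_path: str | None = None
    landmarks_fixed_path: str | None = None
    landmarks_moving_path: str | None = None
    visible_labels: list | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    mi: MIConfig = field(default_factory=MIConfig)
    cc_border_xy: int = 30
    cc_border_z: int = 2
    lung_window: tuple = (-1000.0, -500.0)
    seed: int = 0
    patient: str = ""
    session: str = ""
    output_dir: str | None = None

    def config_hash(self) -> str:
        doc = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudyResult:
    """Transforms, per-stage metrics and provenance of one study."""

    rigid_transform: CompositeTransform
    elastic_transform: CompositeTransform
    metrics: SessionMetrics
    fixed_cropped: ImageVolume
    warped: dict
    diagnostics: dict
    provenance: dict

    def metrics_json(self) -> str:
        doc = {"metrics": self.metrics.as_record(),
               "provenance": self.provenance,
               "diagnostics": self.diagnostics}
        return json.dumps(doc, sort_keys=True, indent=1, default=float)


def _lung_indices(fixed_lungs, warped_img, body, window, fov_z):
    """Per-lung V_E/C_E/JAC of a warped stage against the kVCT lungs.

    The warped image gets its own body mask: after deformation the patient
    outline no longer coincides with the reference body, and air pulled
    inside the reference outline must not masquerade as lung.
    """
    warped_body = extract_body_mask(warped_img)
    lungs = segment_lungs_region_growing(warped_img, window[0], window[1],
                                         body=warped_body)
    left, right = split_left_right(lungs, body=warped_body)
    out = {}
    for side, reg in (("left", left), ("right", right)):
        ct = fixed_lungs[side]
        ct_c, reg_c = restrict_to_common_extent(ct, reg, fov_z)
        out[side] = {
            "ve": volume_error(lung_volume(ct_c), lung_volume(reg_c)),
            "ce": centroid_error(ct_c, reg_c),
            "jac": jaccard_index(ct_c, reg_c),
        }
    return out


def run_study(cfg: StudyConfig,
              fixed: ImageVolume | None = None,
              moving: ImageVolume | None = None,
              landmarks_fixed: LandmarkSet | None = None,
              landmarks_moving: LandmarkSet | None = None) -> StudyResult:
    """Run one complete registration + validation study.

    Images and landmarks may be passed in memory (phantom studies) or read
    from the configured paths.
    """
    if fixed is None:
        fixed = read_image(cfg.fixed_path, modality="kVCT")
    if moving is None:
        moving = read_image(cfg.moving_path, modality="MVCT")
    if landmarks_fixed is None and cfg.landmarks_fixed_path:
        landmarks_fixed = LandmarkSet.read_csv(cfg.landmarks_fixed_path, "kVCT")
    if landmarks_moving is None and cfg.landmarks_moving_path:
        landmarks_moving = LandmarkSet.read_csv(cfg.landmarks_moving_path, "MVCT")

    # --- pre-processing: couch removal, body masking, axial cropping -------
    body_f = extract_body_mask(fixed, cfg.preprocess)
    body_m = extract_body_mask(moving, cfg.preprocess)
    fixed_p = mask_background(fixed, body_f, cfg.preprocess)
    moving_p = mask_background(moving, body_m, cfg.preprocess)
    fixed_c = crop_axial_to_overlap(fixed_p, moving_p)
    body_c = Mask(body_f.voxels[:, :, _crop_slice(fixed_p, fixed_c)],
                  fixed_c.spacing, fixed_c.origin)

    mi = MIConfig(n_bins=cfg.mi.n_bins, sample_fraction=cfg.mi.sample_fraction,
                  seed=cfg.seed, min_samples=cfg.mi.min_samples)

    # --- registration ------------------------------------------------------
    diagnostics = {"rigid": {}, "elastic": {}}
    rigid = register_rigid(fixed_c, moving_p, cfg=mi, fixed_body=body_c,
                           diagnostics=diagnostics["rigid"])
    rigid_T = CompositeTransform(rigid=rigid)
    elastic_T = register_elastic(fixed_c, moving_p, rigid, cfg=mi,
                                 fixed_body=body_c,
                                 diagnostics=diagnostics["elastic"])

    warped = {"rigid": warp_moving_image(moving_p, rigid_T, fixed_c),
              "elastic": warp_moving_image(moving_p, elastic_T, fixed_c)}

    # --- metrics ------------------------------------------------------------
    metrics = SessionMetrics(patient=cfg.patient, session=cfg.session)
    for stage in ("rigid", "elastic"):
        metrics.cc[stage] = correlation_coefficient(
            fixed_c, warped[stage], cfg.cc_border_xy, cfg.cc_border_z)

    low, high = cfg.lung_window
    fixed_lung_mask = segment_lungs_region_growing(fixed_c, low, high, body=body_c)
    fl, fr = split_left_right(fixed_lung_mask, body=body_c)
    fixed_lungs = {"left": fl, "right": fr}
    # common imaged sub-region, trimmed like the CC border: the first/last
    # z planes are interpolated from outside the MVCT and are unreliable
    z0 = fixed_c.origin[2] - 0.5 * fixed_c.spacing[2]
    trim = cfg.cc_border_z * fixed_c.spacing[2]
    fov_z = (z0 + trim, z0 + fixed_c.shape[2] * fixed_c.spacing[2] - trim)
    transforms = {"rigid": rigid_T, "elastic": elastic_T}
    for stage in ("rigid", "elastic"):
        try:
            indices = _lung_indices(fixed_lungs, warped[stage], body_c,
                                    cfg.lung_window, fov_z)
        except DegenerateInputError as exc:
            diagnostics[f"lungs_{stage}"] = str(exc)
            continue
        from .validation import LungIndices
        for side, vals in indices.items():
            metrics.lungs[(stage, side)] = LungIndices(
                volume_error_percent=vals["ve"],
                centroid_error_mm=vals["ce"], jaccard=vals["jac"])

    if landmarks_fixed is not None and landmarks_moving is not None:
        labels = cfg.visible_labels or [
            l for l in landmarks_fixed.labels() if l in landmarks_moving.entries]
        marks = landmarks_fixed.subset(labels)
        for stage, T in transforms.items():
            exclusions: list = []
            mapped = transform_landmarks(marks, T, exclusions)
            per, summary = target_registration_error(mapped, landmarks_moving)
            metrics.tre[stage] = summary
            metrics.tre_per_landmark[stage] = per
            if exclusions:
                diagnostics[f"landmark_exclusions_{stage}"] = exclusions

    provenance = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                  "version": __version__,
                  "elastic_levels": diagnostics["elastic"].get("levels", [])}
    result = StudyResult(rigid_transform=rigid_T, elastic_transform=elastic_T,
                         metrics=metrics, fixed_cropped=fixed_c, warped=warped,
                         diagnostics=diagnostics, provenance=provenance)
    if cfg.output_dir:
        _emit_study(result, cfg)
    return result


def _crop_slice(full: ImageVolume, cropped: ImageVolume) -> slice:
    k0 = int(round((cropped.origin[2] - full.origin[2]) / full.spacing[2]))
    return slice(k0, k0 + cropped.shape[2])


def _emit_study(result: StudyResult, cfg: StudyConfig) -> None:
    os.makedirs(cfg.output_dir, exist_ok=True)
    with open(os.path.join(cfg.output_dir, "metrics.json"), "w") as fh:
        fh.write(result.metrics_json())
    save_transform(result.rigid_transform,
                   os.path.join(cfg.output_dir, "transform_rigid.json"))
    save_transform(result.elastic_transform,
                   os.path.join(cfg.output_dir, "transform_elastic.json"))


def export_difference_png(fixed: ImageVolume, warped: ImageVolume, path,
                          slice_index: int | None = None) -> None:
    """Save a mid-axial |difference| image for visual review."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    k = slice_index if slice_index is not None else fixed.shape[2] // 2
    diff = np.abs(fixed.voxels[:, :, k] - warped.voxels[:, :, k]).T
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(diff, cmap="gray", origin="lower")
    ax.set_title("|fixed - registered|")
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def run_cohort(results) -> "CohortTable":
    """Aggregate several study results (or metric records) into a cohort table."""
    rows = []
    for r in results:
        rows.append(r.metrics if isinstance(r, StudyResult) else r)
    return aggregate_cohort(rows)


# ---------------------------------------------------------------------------
# Phantom validation suite
# ---------------------------------------------------------------------------

@dataclass
class PhantomScenario:
    """One synthetic study: phantom geometry, deformation, MVCT degradation."""

    name: str
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    deformation: DeformationSpec = field(default_factory=DeformationSpec)
    mvct_spacing: tuple = (0.754, 0.754, 4.0)
    fov_z_mm: float | None = 120.0   # axial FOV length, centered; None = full
    noise_sd: float = 30.0
    contrast_scale: float = 0.9


def default_scenarios(seed: int = 0) -> list:
    """One scenario per anatomical-change mode."""
    return [
        PhantomScenario("mediastinal_shift",
                        deformation=DeformationSpec(mode="mediastinal_shift",
                                                    amplitude_mm=10.0, seed=seed)),
        PhantomScenario("atelectasis",
                        deformation=DeformationSpec(mode="atelectasis",
                                                    volume_change_percent=25.0,
                                                    side="left", seed=seed)),
        PhantomScenario("pleural_effusion",
                        deformation=DeformationSpec(mode="pleural_effusion",
                                                    amplitude_mm=10.0,
                                                    side="right", seed=seed)),
        PhantomScenario("body_shrink",
                        deformation=DeformationSpec(mode="body_shrink",
                                                    amplitude_mm=6.0, seed=seed)),
    ]


def run_phantom_scenario(scenario: PhantomScenario, seed: int = 0,
                         compute_lung_indices: bool = True) -> dict:
    """Generate, deform, degrade and register one phantom scenario.

    Returns a report with per-stage ground-truth TRE and (optionally) the
    lung correspondence indices, plus the full study metrics.
    """
    spec = scenario.phantom
    kvct, truth0 = generate_thorax_phantom(spec)
    deformed, truth = apply_synthetic_deformation(kvct, truth0,
                                                  scenario.deformation)
    z_lo = kvct.origin[2] - 0.5 * kvct.spacing[2]
    z_hi = z_lo + kvct.shape[2] * kvct.spacing[2]
    if scenario.fov_z_mm is None:
        fov = None
    else:
        mid = 0.5 * (z_lo + z_hi)
        fov = (max(z_lo, mid - scenario.fov_z_mm / 2),
               min(z_hi, mid + scenario.fov_z_mm / 2))
    mvct = degrade_to_mvct(deformed, spacing=scenario.mvct_spacing, fov_z=fov,
                           noise_sd=scenario.noise_sd,
                           contrast_scale=scenario.contrast_scale,
                           seed=seed + 17)

    # landmarks "visible" in the MVCT: true position inside the MVCT z-FOV,
    # and kVCT position inside the axially cropped registration domain
    mv_z0 = mvct.origin[2] - 0.5 * mvct.spacing[2]
    mv_z1 = mv_z0 + mvct.shape[2] * mvct.spacing[2]
    centers = kvct.voxel_centers_axis(2)
    kept = centers[(centers >= mv_z0) & (centers < mv_z1)]
    crop_lo = kept[0] - 0.5 * kvct.spacing[2]
    crop_hi = kept[-1] + 0.5 * kvct.spacing[2]
    visible = [l for l, p in truth.landmarks_moving.entries.items()
               if mv_z0 <= p[2] < mv_z1
               and crop_lo < truth.landmarks_fixed.entries[l][2] < crop_hi]

    cfg = StudyConfig(seed=seed, patient=scenario.name, session="1",
                      visible_labels=visible or None)
    result = run_study(cfg, fixed=kvct, moving=mvct,
                       landmarks_fixed=truth.landmarks_fixed,
                       landmarks_moving=truth.landmarks_moving)
    report = {"scenario": scenario.name, "seed": seed,
              "visible_landmarks": visible,
              "metrics": result.metrics.as_record()}
    for stage, T in (("rigid", result.rigid_transform),
                     ("elastic", result.elastic_transform)):
        _, summary = ground_truth_error(T, truth, labels=visible or None)
        report[f"ground_truth_tre_{stage}"] = summary
    report["max_voxel_dimension_mm"] = float(
        max(max(kvct.spacing), max(mvct.spacing)))
    return report, result, truth


def run_phantom_validation(scenarios=None, seed: int = 0) -> dict:
    """Run the scenario suite; per-scenario failures are isolated."""
    scenarios = scenarios if scenarios is not None else default_scenarios(seed)
    reports, failures = [], []
    for sc in scenarios:
        try:
            report, _, _ = run_phantom_scenario(sc, seed=seed)
            reports.append(report)
        except TomoregError as exc:
            failures.append({"scenario": sc.name, "error": str(exc)})
    return {"reports": reports, "failures": failures, "seed": seed}


def load_study_config(path) -> StudyConfig:
    """Read a StudyConfig from YAML."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    pp = PreprocessConfig(**doc.pop("preprocess", {}))
    mi = MIConfig(**doc.pop("mi", {}))
    return StudyConfig(preprocess=pp, mi=mi, **doc)
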