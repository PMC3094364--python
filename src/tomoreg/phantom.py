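"""Synthetic thorax phantom with known ground truth.

Generates a kVCT-like HU-calibrated thorax (elliptical body, two lung
ellipsoids, a vertebral column, a detached treatment-couch slab, band-limited
texture and high-contrast spherical landmarks), applies analytically known
smooth deformations emulating the anatomy changes seen over a course of
thoracic radiotherapy (mediastinal shift, atelectasis, pleural effusion,
body-contour shrink), and degrades the result to an MVCT-like scan (coarser
axial sampling, restricted axial field of view, reduced contrast, noise).

Deformations are defined through the resampling (pull-back) map
``psi: deformed point -> source point`` built from compactly supported smooth
bumps, so the deformed image is ``J(q) = I(psi(q))`` exactly.  The forward
registration ground truth ``T = psi^{-1}`` (kVCT frame -> deformed/MVCT
frame) is recovered by fixed-point iteration; landmarks, lung masks and the
dense displacement field are all advected consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy import ndimage

from .errors import UsageError
from .image import AIR_HU, ImageVolume, Mask
from .validation import LandmarkSet

DEFAULT_TISSUES = {"air": -1000.0, "lung": -850.0, "soft": 0.0,
                   "bone": 700.0, "effusion": 20.0}


def _default_landmarks():
    """Landmark catalog in mm relative to the body center.

    Mirrors the anatomical sites used for TRE scoring in thoracic CT:
    carina, bronchial bifurcations, vertebral body, aortic arch, lung
    apices, rib and breast-bone.
    """
    return {
        "carina": (0.0, -4.0, 15.0),
        "bronchial_bifurcation_left": (20.0, -4.0, 0.0),
        "bronchial_bifurcation_right": (-20.0, -4.0, 0.0),
        "vertebral_body": (0.0, 40.0, -30.0),
        "aortic_arch": (5.0, -16.0, 28.0),
        "lung_apex_left": (34.0, -4.0, 50.0),
        "lung_apex_right": (-34.0, -4.0, -50.0),
        "rib_left": (64.0, -18.0, 10.0),
        "breast_bone": (0.0, -48.0, 5.0),
    }


@dataclass
class PhantomSpec:
    """Geometry, tissue model and landmark catalog of the synthetic thorax."""

    shape: tuple = (192, 192, 60)
    spacing: tuple = (0.976, 0.976, 3.27)
    body_semiaxes: tuple = (75.0, 56.0, 150.0)
    lung_semiaxes: tuple = (24.0, 34.0, 64.0)
    lung_offset: tuple = (34.0, -4.0, 0.0)   # mirrored in x for the right lung
    spine_center_y: float = 40.0
    spine_radius: float = 9.0
    tissues: dict = dc_field(default_factory=lambda: dict(DEFAULT_TISSUES))
    texture_amplitude: float = 20.0
    texture_correlation_voxels: float = 1.5
    landmark_offsets: dict = dc_field(default_factory=_default_landmarks)
    landmark_radius_voxels: float = 3.0
    landmark_delta_hu: float = 300.0
    couch: bool = True
    couch_hu: float = 150.0
    seed: int = 0


@dataclass
class DeformationSpec:
    """One synthetic anatomical change.

    ``amplitude_mm`` bounds the displacement magnitude; ``volume_change_percent``
    (atelectasis only) is the target percent reduction of the affected lung
    volume; ``side`` selects the lung for lateralized modes.
    """

    mode: str = "smooth_random"
    amplitude_mm: float = 10.0
    volume_change_percent: float = 25.0
    effusion_fraction: float = 0.20
    side: str = "left"
    n_bumps: int = 3
    bump_radius_mm: float = 60.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Known deformation, landmarks and lung masks for a phantom pair."""

    displacement: np.ndarray               # (*shape, 3) mm, on the kVCT grid
    landmarks_fixed: LandmarkSet
    landmarks_moving: LandmarkSet
    lung_masks_fixed: dict
    lung_masks_moving: dict
    spacing: np.ndarray = None
    origin: np.ndarray = None

    def lung_volume(self, side: str, frame: str = "fixed") -> float:
        masks = self.lung_masks_fixed if frame == "fixed" else self.lung_masks_moving
        return masks[side].count() * masks[side].voxel_volume


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _grid_points(shape, spacing, origin):
    axes = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _lung_centers(spec: PhantomSpec, body_center):
    off = np.asarray(spec.lung_offset)
    left = body_center + off
    right = body_center + off * np.array([-1.0, 1.0, 1.0])
    return {"left": left, "right": right}


def _ellipsoid_membership(X, Y, Z, center, semiaxes):
    return (((X - center[0]) / semiaxes[0]) ** 2
            + ((Y - center[1]) / semiaxes[1]) ** 2
            + ((Z - center[2]) / semiaxes[2]) ** 2) <= 1.0


def generate_thorax_phantom(spec: PhantomSpec | None = None):
    """Build the kVCT phantom volume and its identity ground truth."""
    spec = spec or PhantomSpec()
    shape = tuple(int(n) for n in spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    origin = np.zeros(3)
    extent = np.asarray(shape) * spacing
    body_center = origin + 0.5 * (np.asarray(shape) - 1) * spacing
    X, Y, Z = _grid_points(shape, spacing, origin)

    hu = np.full(shape, spec.tissues["air"], dtype=float)
    body = _ellipsoid_membership(X, Y, Z, body_center, spec.body_semiaxes)
    hu[body] = spec.tissues["soft"]
    spine = (((X - body_center[0]) ** 2
              + (Y - (body_center[1] + spec.spine_center_y)) ** 2)
             <= spec.spine_radius ** 2) & body
    hu[spine] = spec.tissues["bone"]
    centers = _lung_centers(spec, body_center)
    # chest wall must stay at least ~2 in-plane voxels thick everywhere, or
    # noise/warping opens the lungs to the exterior air
    body_core = ndimage.binary_erosion(body, iterations=2, border_value=1)
    lung_masks = {}
    for side, c in centers.items():
        m = _ellipsoid_membership(X, Y, Z, c, spec.lung_semiaxes)
        if not np.all(body_core[m]):
            raise UsageError("lung ellipsoid too close to the body surface")
        hu[m] = spec.tissues["lung"]
        lung_masks[side] = Mask(m, spacing.copy(), origin.copy())

    if spec.texture_amplitude > 0:
        # multi-scale texture: real parenchyma/soft tissue has structure at
        # every scale, which keeps MI informative under coarse-level blur
        rng = np.random.default_rng(spec.seed)
        tex = np.zeros(shape)
        for sigma in (spec.texture_correlation_voxels, 4.0, 10.0):
            comp = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
            tex += comp / max(comp.std(), 1e-12)
        tex *= spec.texture_amplitude / max(tex.std(), 1e-12)
        hu[body] += tex[body]

    if spec.couch:
        y0, y1 = 0.90 * extent[1], 0.96 * extent[1]
        x0, x1 = 0.20 * extent[0], 0.80 * extent[0]
        slab = (Y >= y0) & (Y < y1) & (X >= x0) & (X < x1)
        hu[slab] = spec.couch_hu

    marks = {}
    for label, off in spec.landmark_offsets.items():
        p = body_center + np.asarray(off, dtype=float)
        marks[label] = p
        rad = spec.landmark_radius_voxels * spacing
        sphere = _ellipsoid_membership(X, Y, Z, p, rad)
        hu[sphere] += spec.landmark_delta_hu

    img = ImageVolume(voxels=hu, spacing=spacing, origin=origin,
                      modality="synthetic")
    lmset = LandmarkSet(marks, frame="kVCT")
    truth = GroundTruth(
        displacement=np.zeros(shape + (3,), dtype=np.float32),
        landmarks_fixed=lmset,
        landmarks_moving=LandmarkSet(dict(marks), frame="MVCT"),
        lung_masks_fixed=lung_masks,
        lung_masks_moving={s: Mask(m.voxels.copy(), spacing.copy(), origin.copy())
                           for s, m in lung_masks.items()},
        spacing=spacing.copy(), origin=origin.copy())
    return img, truth


# ---------------------------------------------------------------------------
# Deformation machinery
# ---------------------------------------------------------------------------

DENSIFY_GAIN = 0.6  # HU blend per unit of volumetric compression


def _bump(r):
    """C1 compact bump: cos^2(pi r / 2) on r < 1, zero outside."""
    out = np.zeros_like(r)
    inside = r < 1.0
    out[inside] = np.cos(0.5 * np.pi * r[inside]) ** 2
    return out


class _PullbackField:
    """psi(q) = q + u(q): deformed-frame point -> source-frame point."""

    def __init__(self, extent, taper_mm=10.0):
        self.terms = []
        self.extent = np.asarray(extent, dtype=float)
        self.taper_mm = taper_mm

    def add_radial(self, center, radius, gain):
        """u = gain * (q - c) * bump(|q - c| / radius); gain > 0 contracts."""
        self.terms.append(("radial", np.asarray(center, float), float(radius),
                           float(gain)))

    def add_translation(self, center, radius, vector):
        """u = vector * bump(|q - c| / radius)."""
        self.terms.append(("translation", np.asarray(center, float),
                           float(radius), np.asarray(vector, float)))

    def add_shell(self, center, semiaxes, width, gain_mm):
        """Outward radial bump on an ellipsoidal shell (body-contour shrink)."""
        self.terms.append(("shell", np.asarray(center, float),
                           (np.asarray(semiaxes, float), float(width)),
                           float(gain_mm)))

    def _taper(self, q):
        t = np.ones(len(q))
        w = self.taper_mm
        for a in range(3):
            lo = np.clip(q[:, a] / w, 0.0, 1.0)
            hi = np.clip((self.extent[a] - q[:, a]) / w, 0.0, 1.0)
            t *= lo * hi
        return t

    def displacement(self, q):
        q = np.atleast_2d(q)
        u = np.zeros_like(q)
        for kind, center, geom, gain in self.terms:
            if kind == "radial":
                rel = q - center
                r = np.linalg.norm(rel, axis=1) / geom
                u += gain * rel * _bump(r)[:, None]
            elif kind == "translation":
                rel = q - center
                r = np.linalg.norm(rel, axis=1) / geom
                u += gain[None, :] * _bump(r)[:, None]
            elif kind == "shell":
                semi, width = geom
                rel = (q - center) / semi
                rho = np.linalg.norm(rel, axis=1)
                radial = np.linalg.norm(q - center, axis=1)
                direction = np.where(radial[:, None] > 1e-9,
                                     (q - center) / np.maximum(radial, 1e-9)[:, None],
                                     0.0)
                u += gain * direction * _bump(np.abs(rho - 1.0) / width)[:, None]
        return u * self._taper(q)[:, None]

    def map_points(self, q):
        return np.atleast_2d(q) + self.displacement(q)

    def invert(self, p, n_iter=40, tol=1e-10):
        """Solve psi(q) = p by fixed-point iteration q <- p - u(q)."""
        p = np.atleast_2d(p)
        q = p.copy()
        for _ in range(n_iter):
            q_new = p - self.displacement(q)
            if np.max(np.abs(q_new - q)) < tol:
                q = q_new
                break
            q = q_new
        return q


def _field_on_grid(psi: _PullbackField, shape, spacing, origin, chunk=400_000):
    """u(q) evaluated at every voxel center -> (*shape, 3)."""
    X, Y, Z = _grid_points(shape, spacing, origin)
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    out = np.empty_like(pts)
    for s in range(0, len(pts), chunk):
        out[s:s + chunk] = psi.displacement(pts[s:s + chunk])
    return out.reshape(shape + (3,))


def _jacobian_determinant(u_grid, spacing):
    """det(I + du/dq) from a gridded displacement field."""
    grads = []
    for comp in range(3):
        g = np.gradient(u_grid[..., comp], *spacing, edge_order=1)
        grads.append(g)
    J = np.empty(u_grid.shape[:3] + (3, 3))
    for i in range(3):
        for j in range(3):
            J[..., i, j] = (1.0 if i == j else 0.0) + grads[i][j]
    return np.linalg.det(J)


def _warp_by_pullback(values, psi, shape, spacing, origin, order=1, cval=AIR_HU):
    X, Y, Z = _grid_points(shape, spacing, origin)
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    src = psi.map_points(pts)
    idx = (src - origin) / spacing
    out = ndimage.map_coordinates(values.astype(float), idx.T, order=order,
                                  mode="constant", cval=cval)
    return out.reshape(shape)


def apply_synthetic_deformation(img: ImageVolume, truth: GroundTruth,
                                d: DeformationSpec):
    """Warp the phantom by a known smooth field and update the ground truth.

    Returns (deformed image, new GroundTruth).  The Jacobian of the pull-back
    map is checked numerically; foldover raises.
    """
    shape, spacing, origin = img.shape, img.spacing, img.origin
    extent = np.asarray(shape) * spacing
    body_center = origin + 0.5 * (np.asarray(shape) - 1) * spacing
    psi = _PullbackField(extent)
    rng = np.random.default_rng(d.seed)
    lung_center = None
    lung_semi = None
    if truth.lung_masks_fixed:
        side_mask = truth.lung_masks_fixed[d.side]
        com = np.asarray(ndimage.center_of_mass(side_mask.voxels))
        lung_center = origin + com * spacing
        nz = np.asarray(np.nonzero(side_mask.voxels))
        half = (nz.max(axis=1) - nz.min(axis=1) + 1) * spacing / 2
        lung_semi = half

    if d.mode == "mediastinal_shift":
        med_center = body_center + np.array([0.0, -6.0, 0.0])
        psi.add_translation(med_center, 0.55 * min(extent[0], extent[1]),
                            np.array([-d.amplitude_mm, 0.0, 0.0]))
    elif d.mode == "atelectasis":
        gain = _calibrate_atelectasis(psi, img, truth, d, lung_center,
                                      lung_semi, shape, spacing, origin)
        psi.add_radial(lung_center, 1.6 * float(np.max(lung_semi)), gain)
    elif d.mode == "pleural_effusion":
        # fluid at the lung base compresses the parenchyma upward
        psi.add_translation(lung_center, 1.4 * float(np.max(lung_semi)),
                            np.array([0.0, 0.0, d.amplitude_mm]))
    elif d.mode == "body_shrink":
        # inward contour shift: pull-back points outward near the body shell;
        # weight loss also drags interior anatomy, modeled as mild bumps
        body_semi = _body_semiaxes_from_masks(truth, extent)
        psi.add_shell(body_center, body_semi, 0.32, d.amplitude_mm)
        for _ in range(2):
            c = body_center + rng.uniform(-0.2, 0.2, 3) * extent
            vec = rng.uniform(-1.0, 1.0, 3)
            vec *= 0.8 * d.amplitude_mm / max(np.linalg.norm(vec), 1e-9)
            psi.add_translation(c, 80.0, vec)
    elif d.mode == "smooth_random":
        for _ in range(d.n_bumps):
            c = body_center + (rng.uniform(-0.25, 0.25, 3)
                               * np.array([extent[0], extent[1], extent[2]]))
            vec = rng.uniform(-1.0, 1.0, 3)
            vec *= d.amplitude_mm / max(np.linalg.norm(vec), 1e-9)
            vec *= rng.uniform(0.5, 1.0)
            psi.add_translation(c, d.bump_radius_mm, vec)
    elif d.mode != "zero":
        raise UsageError(f"unknown deformation mode: {d.mode}")

    u_grid = _field_on_grid(psi, shape, spacing, origin)
    jdet = _jacobian_determinant(u_grid, spacing)
    if np.any(jdet <= 0):
        raise UsageError("deformation folds over (non-positive Jacobian); "
                         "reduce the amplitude")

    warped = _warp_by_pullback(img.voxels, psi, shape, spacing, origin)

    # lung masks in the deformed frame: membership of psi(q), then HU window
    moving_masks = {}
    for side, m in truth.lung_masks_fixed.items():
        wm = _warp_by_pullback(m.voxels.astype(float), psi, shape, spacing,
                               origin, order=1, cval=0.0) >= 0.5
        moving_masks[side] = wm

    if d.mode == "atelectasis":
        # compressed parenchyma densifies toward fluid/soft HU
        t = np.clip((jdet - 1.0) * DENSIFY_GAIN, 0.0, 1.0)
        region = moving_masks[d.side]
        warped[region] = ((1 - t) * warped + t * DEFAULT_TISSUES["effusion"])[region]
    if d.mode == "pleural_effusion":
        region = moving_masks[d.side]
        X, Y, Z = _grid_points(shape, spacing, origin)
        zvals = Z[region]
        level = np.quantile(zvals, d.effusion_fraction)
        effusion_region = region & (Z <= level)
        warped[effusion_region] = DEFAULT_TISSUES["effusion"]

    # keep truth masks consistent with the HU model under the [-1000,-500] window
    window = (warped >= -1000.0) & (warped <= -500.0)
    lung_masks_moving = {side: Mask(wm & window, spacing.copy(), origin.copy())
                         for side, wm in moving_masks.items()}

    # forward map T = psi^{-1} on the grid and at the landmarks
    X, Y, Z = _grid_points(shape, spacing, origin)
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    disp = np.empty_like(pts)
    chunk = 400_000
    for s in range(0, len(pts), chunk):
        q = psi.invert(pts[s:s + chunk])
        disp[s:s + chunk] = q - pts[s:s + chunk]
    displacement = disp.reshape(shape + (3,)).astype(np.float32)

    marks_fixed = truth.landmarks_fixed
    moved = psi.invert(marks_fixed.points())
    residual = np.abs(psi.map_points(moved) - marks_fixed.points()).max()
    if residual > 1e-6:
        raise UsageError("landmark advection failed to converge")
    landmarks_moving = LandmarkSet(
        {l: moved[i] for i, l in enumerate(marks_fixed.labels())}, frame="MVCT")

    out_img = replace(img, voxels=warped)
    new_truth = GroundTruth(
        displacement=displacement,
        landmarks_fixed=LandmarkSet(dict(marks_fixed.entries), frame="kVCT"),
        landmarks_moving=landmarks_moving,
        lung_masks_fixed=truth.lung_masks_fixed,
        lung_masks_moving=lung_masks_moving,
        spacing=spacing.copy(), origin=origin.copy())
    return out_img, new_truth


def _body_semiaxes_from_masks(truth: GroundTruth, extent):
    # body shell location estimated from the lung extent (lungs sit inside
    # the body with a known construction margin); fall back to image extent
    return np.array([0.40 * extent[0], 0.30 * extent[1], 0.80 * extent[2]])


def _calibrate_atelectasis(psi, img, truth, d, lung_center, lung_semi,
                           shape, spacing, origin):
    """Bisection on the radial gain to hit the target lung volume reduction.

    The target refers to the final truth mask: warped lung membership AND a
    warped HU (with compression densification) still inside the lung window.
    Trials evaluate exactly that criterion on the lung bounding box.
    """
    target = 1.0 - d.volume_change_percent / 100.0
    mask = truth.lung_masks_fixed[d.side].voxels
    # evaluate volume ratio on the lung bounding box only
    nz = np.asarray(np.nonzero(mask))
    lo = np.maximum(nz.min(axis=1) - 8, 0)
    hi = np.minimum(nz.max(axis=1) + 9, np.asarray(shape))
    sub = tuple(slice(a, b) for a, b in zip(lo, hi))
    box = tuple(int(b - a) for a, b in zip(lo, hi))
    axes = [origin[a] + np.arange(lo[a], hi[a]) * spacing[a] for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    base = int(mask[sub].sum())
    radius = 1.6 * float(np.max(lung_semi))

    def ratio(gain):
        trial = _PullbackField(psi.extent)
        trial.add_radial(lung_center, radius, gain)
        disp = trial.displacement(pts)
        idx = (pts + disp - origin) / spacing
        vals = ndimage.map_coordinates(mask.astype(float), idx.T, order=1,
                                       mode="constant", cval=0.0)
        hu = ndimage.map_coordinates(img.voxels.astype(float), idx.T,
                                     order=1, mode="constant", cval=AIR_HU)
        jdet = _jacobian_determinant(disp.reshape(box + (3,)), spacing)
        t = np.clip((jdet.ravel() - 1.0) * DENSIFY_GAIN, 0.0, 1.0)
        hu = (1 - t) * hu + t * DEFAULT_TISSUES["effusion"]
        keep = (vals >= 0.5) & (hu >= -1000.0) & (hu <= -500.0)
        return float(keep.sum()) / base

    g_lo, g_hi = 0.0, 0.45
    for _ in range(18):
        mid = 0.5 * (g_lo + g_hi)
        if ratio(mid) > target:
            g_lo = mid
        else:
            g_hi = mid
    return 0.5 * (g_lo + g_hi)


# ---------------------------------------------------------------------------
# MVCT degradation
# ---------------------------------------------------------------------------

def degrade_to_mvct(img: ImageVolume, spacing=(0.754, 0.754, 4.0),
                    fov_z=None, noise_sd: float = 30.0,
                    contrast_scale: float = 0.9, seed: int = 0) -> ImageVolume:
    """Resample to MVCT geometry, restrict the axial FOV, degrade contrast/noise.

    ``fov_z`` is the physical z-interval (mm) retained; default keeps the full
    z-extent.  Contrast is compressed linearly about air (-1000 HU) and white
    Gaussian noise of ``noise_sd`` HU is added; deterministic given ``seed``.
    """
    spacing = np.asarray(spacing, dtype=float)
    z_lo = img.origin[2] - 0.5 * img.spacing[2]
    z_hi = z_lo + img.shape[2] * img.spacing[2]
    if fov_z is None:
        fov_z = (z_lo, z_hi)
    f0, f1 = float(fov_z[0]), float(fov_z[1])
    if f0 < z_lo - 1e-6 or f1 > z_hi + 1e-6 or f1 <= f0:
        raise UsageError("MVCT fov_z must be a non-empty interval inside the image")
    n_xy = np.floor(img.extent[:2] / spacing[:2]).astype(int)
    n_z = int(np.floor((f1 - f0) / spacing[2]))
    if n_z < 1:
        raise UsageError("axial FOV shorter than one MVCT slice")
    new_origin = np.array([img.origin[0], img.origin[1], f0 + 0.5 * spacing[2]])
    axes = [new_origin[a] + np.arange((*n_xy, n_z)[a]) * spacing[a]
            for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    idx = np.stack([(X - img.origin[0]) / img.spacing[0],
                    (Y - img.origin[1]) / img.spacing[1],
                    (Z - img.origin[2]) / img.spacing[2]])
    vox = ndimage.map_coordinates(img.voxels.astype(float),
                                  idx.reshape(3, -1), order=1,
                                  mode="constant", cval=AIR_HU)
    vox = vox.reshape(X.shape)
    vox = AIR_HU + contrast_scale * (vox - AIR_HU)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vox = vox + rng.normal(0.0, noise_sd, size=vox.shape)
    return ImageVolume(voxels=vox, spacing=spacing, origin=new_origin,
                       modality="MVCT")


# ---------------------------------------------------------------------------
# Ground-truth scoring
# ---------------------------------------------------------------------------

def ground_truth_error(estimated, truth: GroundTruth, labels=None):
    """Residual (mm) between estimated and true landmark mappings.

    Returns (per_label: dict, summary: dict) like the TRE computation, with
    the true deformed-frame landmark positions standing in for expert
    detection.
    """
    from .transforms import transform_point
    if labels is None:
        labels = truth.landmarks_fixed.labels()
    missing = [l for l in labels if l not in truth.landmarks_fixed.entries]
    if missing:
        raise UsageError(f"unknown landmark labels: {missing}")
    residual = {}
    for label in labels:
        p = truth.landmarks_fixed.entries[label]
        mapped = transform_point(estimated, p)
        residual[label] = float(np.linalg.norm(mapped
                                               - truth.landmarks_moving.entries[label]))
    values = np.array(list(residual.values()))
    summary = {"mean": float(values.mean()),
               "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
               "max": float(values.max()), "n": int(len(values))}
    return residual, summary
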