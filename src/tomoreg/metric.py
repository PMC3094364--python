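"""Mattes-form mutual information: value and analytic gradient.

The joint intensity distribution is estimated from a random subset of fixed
voxel centers with Parzen windows — a zero-order (box) window on the fixed
intensity axis and a cubic B-spline window on the moving axis — and the
negative mutual information

    S = - sum_{k,l} P(k,l) log( P(k,l) / (P_F(k) P_M(l)) )

is returned together with its exact gradient with respect to the transform
parameters (rigid Euler parameters, or the B-spline coefficient lattice).
The moving image is evaluated by trilinear interpolation, whose analytic
spatial derivative closes the chain rule, so the returned gradient is the
exact derivative of the implemented objective.

Samples whose transformed position leaves the moving volume are dropped and
the distribution renormalized over the usable ones; if too few remain the
metric raises, which signals gross misalignment or over-cropping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSamplingError, UsageError
from .image import ImageVolume, Mask
from .transforms import (BSplineTransform, RigidTransform, bspline3_dweights,
                         bspline3_weights)

_PAD = 2  # guard bins on each end of the moving intensity axis


@dataclass
class MIConfig:
    """Metric configuration.

    n_bins is the histogram resolution per intensity axis (50 is the
    customary value for this Parzen formulation); sample_fraction is the
    fraction of fixed body voxels used; min_samples guards against the joint
    distribution collapsing when samples leave the moving field of view.
    """

    n_bins: int = 50
    sample_fraction: float = 1.0
    seed: int = 0
    min_samples: int = 1000

    def __post_init__(self):
        if not (0.0 < self.sample_fraction <= 1.0):
            raise UsageError("sample_fraction must lie in (0, 1]")
        if self.n_bins < 8:
            raise UsageError("n_bins must be >= 8")


def sample_fixed_points(fixed: ImageVolume, body: Mask, fraction: float,
                        seed: int, min_samples: int = 1) -> np.ndarray:
    """Uniform draw without replacement of body voxel centers.

    ``fraction`` is a percentage in (0, 100]; the draw has size
    round(fraction/100 * |body|) and is reproducible given ``seed``.
    """
    if not (0.0 < fraction <= 100.0):
        raise UsageError("sampling fraction must lie in (0, 100] percent")
    flat = np.flatnonzero(body.voxels)
    total = flat.size
    if total == 0:
        raise DegenerateSamplingError("body mask is empty")
    n = int(round(fraction / 100.0 * total))
    n = max(n, 1)
    if n < min_samples:
        raise DegenerateSamplingError(
            f"sampling would yield {n} points < min_samples={min_samples}")
    if n >= total:
        chosen = flat
    else:
        rng = np.random.default_rng(seed)
        chosen = np.sort(rng.choice(total, size=n, replace=False))
        chosen = flat[chosen]
    idx = np.stack(np.unravel_index(chosen, body.shape), axis=-1).astype(float)
    return body.origin + idx * body.spacing


def interpolate_with_gradient(img: ImageVolume, points: np.ndarray):
    """Trilinear interpolation and its spatial gradient at physical points.

    Returns (values, gradient_mm, inside): gradient is d(intensity)/d(mm)
    per axis; ``inside`` flags points within the voxel-center bounding box.
    Values/gradients of outside points are computed at the clamped position
    and should be masked by the caller.
    """
    vox = img.voxels
    idx = (np.atleast_2d(points) - img.origin) / img.spacing
    hi = np.asarray(vox.shape) - 1
    inside = np.all((idx >= 0.0) & (idx <= hi), axis=1)
    idxc = np.clip(idx, 0.0, hi - 1e-9)
    i0 = np.minimum(idxc.astype(int), np.asarray(vox.shape) - 2)
    f = idxc - i0
    nx, ny, nz = vox.shape
    flat = vox.reshape(-1)
    base = (i0[:, 0] * ny + i0[:, 1]) * nz + i0[:, 2]
    sx, sy, sz = ny * nz, nz, 1
    c000 = flat[base]
    c100 = flat[base + sx]
    c010 = flat[base + sy]
    c001 = flat[base + sz]
    c110 = flat[base + sx + sy]
    c101 = flat[base + sx + sz]
    c011 = flat[base + sy + sz]
    c111 = flat[base + sx + sy + sz]
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
    gx, gy, gz = 1 - fx, 1 - fy, 1 - fz
    # interpolate over z, then y, then x
    c00 = c000 * gz + c001 * fz
    c01 = c010 * gz + c011 * fz
    c10 = c100 * gz + c101 * fz
    c11 = c110 * gz + c111 * fz
    c0 = c00 * gy + c01 * fy
    c1 = c10 * gy + c11 * fy
    value = c0 * gx + c1 * fx
    d_dx = c1 - c0
    d_dy = (c01 - c00) * gx + (c11 - c10) * fx
    dz00 = c001 - c000
    dz01 = c011 - c010
    dz10 = c101 - c100
    dz11 = c111 - c110
    d_dz = ((dz00 * gy + dz01 * fy) * gx + (dz10 * gy + dz11 * fy) * fx)
    grad = np.stack([d_dx, d_dy, d_dz], axis=-1) / img.spacing
    return value, grad, inside


class MattesMIMetric:
    """Negative mutual information over a fixed set of sample points.

    The fixed-intensity bin of every sample and the moving intensity scaling
    are frozen at construction, so repeated evaluations during optimization
    share all histogram bookkeeping.
    """

    def __init__(self, fixed: ImageVolume, moving: ImageVolume,
                 points: np.ndarray, cfg: MIConfig | None = None):
        self.cfg = cfg or MIConfig()
        self.moving = moving
        self.points = np.atleast_2d(np.asarray(points, dtype=float))
        nb = self.cfg.n_bins
        fvals, _, _ = interpolate_with_gradient(fixed, self.points)
        fmin, fmax = float(fvals.min()), float(fvals.max())
        width = (fmax - fmin) / nb
        if width <= 0:
            self.fixed_bins = np.zeros(len(self.points), dtype=int)
            self.fixed_constant = True
        else:
            self.fixed_bins = np.clip(((fvals - fmin) / width).astype(int), 0, nb - 1)
            self.fixed_constant = False
        mmin = float(moving.voxels.min())
        mmax = float(moving.voxels.max())
        self.m_min = mmin
        denom = nb - 1 - 2 * _PAD
        self.m_scale = (mmax - mmin) / denom if mmax > mmin else 0.0
        self.moving_constant = self.m_scale == 0.0

    # -- core histogram machinery ------------------------------------------
    def _evaluate(self, mapped_points: np.ndarray):
        """Value, per-sample d(-MI)/d(moving intensity), moving gradient, mask."""
        nb = self.cfg.n_bins
        mvals, mgrad, inside = interpolate_with_gradient(self.moving, mapped_points)
        n_use = int(inside.sum())
        threshold = max(2, min(self.cfg.min_samples,
                               int(np.ceil(0.25 * len(mapped_points)))))
        if n_use < threshold:
            raise DegenerateSamplingError(
                f"only {n_use} of {len(mapped_points)} samples map inside the "
                f"moving volume (threshold {threshold})")
        if self.moving_constant or self.fixed_constant:
            return 0.0, np.zeros(len(mapped_points)), mgrad, inside
        k = self.fixed_bins[inside]
        eta = (mvals[inside] - self.m_min) / self.m_scale + _PAD
        eta = np.clip(eta, _PAD, nb - 1 - _PAD)
        i0 = np.minimum(eta.astype(int), nb - 2 - _PAD)
        u = eta - i0
        w = bspline3_weights(u)      # (n, 4) for bins i0-1 .. i0+2
        dw = bspline3_dweights(u)
        joint = np.zeros(nb * nb)
        base = k * nb + (i0 - 1)
        for j in range(4):
            joint += np.bincount(base + j, weights=w[:, j], minlength=nb * nb)
        joint /= n_use
        joint = joint.reshape(nb, nb)
        p_f = joint.sum(axis=1)
        p_m = joint.sum(axis=0)
        pos = joint > 0
        log_ratio = np.zeros_like(joint)
        log_ratio[pos] = np.log(joint[pos] / (p_f[:, None] * p_m[None, :])[pos])
        mi = float((joint[pos] * log_ratio[pos]).sum())
        # d MI / d eta_i = (1/N) sum_j dw_j * log(P(k_i, l_j) / P_M(l_j))
        log_pm_ratio = np.zeros_like(joint)
        log_pm_ratio[pos] = np.log(joint[pos] / p_m[None, :].repeat(nb, axis=0)[pos])
        dmi_deta = np.zeros(len(eta))
        for j in range(4):
            dmi_deta += dw[:, j] * log_pm_ratio[k, i0 - 1 + j]
        dmi_deta /= n_use
        # d(-MI)/d m_i, zero for dropped samples
        dneg = np.zeros(len(mapped_points))
        dneg[inside] = -dmi_deta / self.m_scale
        return -mi, dneg, mgrad, inside

    # -- rigid parameterization --------------------------------------------
    def value_and_gradient_rigid(self, params: np.ndarray, center: np.ndarray):
        """-MI and gradient w.r.t. (rx, ry, rz, tx, ty, tz)."""
        rigid = RigidTransform.from_parameters(params, center)
        mapped = rigid.transform_points(self.points)
        value, dneg, mgrad, inside = self._evaluate(mapped)
        g = np.zeros(6)
        if np.any(dneg):
            coeff = dneg[:, None] * mgrad       # d(-MI)/d T(p), (n, 3)
            rel = self.points - center
            rx, ry, rz = params[:3]
            dR = _euler_zyx_derivatives(rx, ry, rz)
            for a in range(3):
                g[a] = float((coeff * (rel @ dR[a].T)).sum())
            g[3:] = coeff.sum(axis=0)
        return value, g

    # -- B-spline parameterization ------------------------------------------
    def prepare_bspline(self, rigid: RigidTransform, bspline: BSplineTransform):
        """Freeze rigidly-mapped points and the sparse FFD basis at the samples."""
        self._rigid_mapped = rigid.transform_points(self.points)
        self._basis = bspline.sparse_basis(self.points)
        self._grid_shape = bspline.grid_size
        # total basis weight per control point; points with (almost) no
        # sample support sit in flat directions of the objective
        self.support = np.asarray(self._basis.sum(axis=0)).ravel()

    def value_and_gradient_bspline(self, coef_flat: np.ndarray):
        """-MI and gradient w.r.t. the flattened coefficient lattice (mm)."""
        coef = coef_flat.reshape(-1, 3)
        mapped = self._rigid_mapped + self._basis @ coef
        value, dneg, mgrad, inside = self._evaluate(mapped)
        coeff = dneg[:, None] * mgrad
        grad = self._basis.T @ coeff
        return value, grad.ravel()


def _euler_zyx_derivatives(rx, ry, rz):
    """d(Rz Ry Rx)/d(rx, ry, rz) as three 3x3 matrices."""
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    dRx = np.array([[0, 0, 0], [0, -sx, -cx], [0, cx, -sx]])
    dRy = np.array([[-sy, 0, cy], [0, 0, 0], [-cy, 0, -sy]])
    dRz = np.array([[-sz, -cz, 0], [cz, -sz, 0], [0, 0, 0]])
    return [Rz @ Ry @ dRx, Rz @ dRy @ Rx, dRz @ Ry @ Rx]


def mattes_mi_value_gradient(fixed: ImageVolume, moving: ImageVolume,
                             transform, points: np.ndarray,
                             cfg: MIConfig | None = None):
    """One-shot -MI value and gradient for a composite transform.

    The gradient is taken with respect to the transform's free parameters:
    the 6 rigid parameters when the composite has no FFD, otherwise the
    flattened B-spline coefficient lattice (rigid held fixed).
    """
    metric = MattesMIMetric(fixed, moving, points, cfg)
    bspline = getattr(transform, "bspline", None)
    rigid = getattr(transform, "rigid", transform)
    if bspline is None:
        return metric.value_and_gradient_rigid(rigid.as_parameters(), rigid.center)
    metric.prepare_bspline(rigid, bspline)
    return metric.value_and_gradient_bspline(bspline.coefficients.ravel())
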