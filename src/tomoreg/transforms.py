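"""Spatial transform model: global rigid motion plus a cubic B-spline FFD.

The composite transform is additive in physical space,

    T(p) = Rigid(p) + D(p),

where ``D`` is a free-form deformation: a tensor-product cubic B-spline
expansion over a regular control-point lattice defined on the fixed-image
physical domain.  All coordinates and displacements are in millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import factorized

from .errors import DegenerateInputError, DomainError, UsageError

# ---------------------------------------------------------------------------
# Cubic B-spline basis
# ---------------------------------------------------------------------------

def bspline3_weights(t: np.ndarray) -> np.ndarray:
    """The four cubic B-spline basis values for fractional offsets t in [0,1).

    Returns shape (len(t), 4): weights for control points i-1, i, i+1, i+2.
    """
    t = np.asarray(t, dtype=float)
    t2, t3 = t * t, t * t * t
    return np.stack([
        (1 - 3 * t + 3 * t2 - t3) / 6.0,
        (4 - 6 * t2 + 3 * t3) / 6.0,
        (1 + 3 * t + 3 * t2 - 3 * t3) / 6.0,
        t3 / 6.0,
    ], axis=-1)


def bspline3_dweights(t: np.ndarray) -> np.ndarray:
    """Derivatives of the four basis values with respect to t."""
    t = np.asarray(t, dtype=float)
    t2 = t * t
    return np.stack([
        (-3 + 6 * t - 3 * t2) / 6.0,
        (-12 * t + 9 * t2) / 6.0,
        (3 + 6 * t - 9 * t2) / 6.0,
        3 * t2 / 6.0,
    ], axis=-1)


# ---------------------------------------------------------------------------
# Rigid transform
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Euler rigid motion: rotation about ``center`` followed by translation.

    ``rotation`` holds the (rx, ry, rz) angles in radians, composed as
    R = Rz @ Ry @ Rx.  ``T(p) = R (p - center) + center + translation``.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.center = np.asarray(self.center, dtype=float)

    def matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        R = self.matrix()
        return (points - self.center) @ R.T + self.center + self.translation

    def inverse(self) -> "RigidTransform":
        """Exact inverse as an affine map expressed in the same parameterization."""
        R = self.matrix()
        inv = RigidTransform(center=self.center.copy())
        # solve Euler angles of R^T (same ZYX convention)
        Rt = R.T
        ry = np.arcsin(-np.clip(Rt[2, 0], -1.0, 1.0))
        if np.isclose(np.cos(ry), 0.0):
            rx = np.arctan2(-Rt[1, 2], Rt[1, 1])
            rz = 0.0
        else:
            rx = np.arctan2(Rt[2, 1], Rt[2, 2])
            rz = np.arctan2(Rt[1, 0], Rt[0, 0])
        inv.rotation = np.array([rx, ry, rz])
        inv.translation = -Rt @ self.translation
        return inv

    def as_parameters(self) -> np.ndarray:
        return np.concatenate([self.rotation, self.translation])

    @classmethod
    def from_parameters(cls, params, center) -> "RigidTransform":
        params = np.asarray(params, dtype=float)
        return cls(rotation=params[:3].copy(), translation=params[3:].copy(),
                   center=np.asarray(center, dtype=float).copy())


# ---------------------------------------------------------------------------
# B-spline free-form deformation
# ---------------------------------------------------------------------------

@dataclass
class BSplineTransform:
    """Displacement field D(p) as a tensor-product cubic B-spline expansion.

    The control lattice has ``grid_size`` points per axis, spaced by
    ``grid_spacing`` mm starting at ``grid_origin``; ``coefficients`` has
    shape (nx, ny, nz, 3) holding per-axis displacements in mm.  The lattice
    covers the image domain plus the one-control-point cubic support margin
    on every side, so D is defined on the whole domain.
    """

    grid_origin: np.ndarray
    grid_spacing: np.ndarray
    grid_size: tuple
    coefficients: np.ndarray
    domain_origin: np.ndarray = None
    domain_extent: np.ndarray = None

    def __post_init__(self):
        self.grid_origin = np.asarray(self.grid_origin, dtype=float)
        self.grid_spacing = np.asarray(self.grid_spacing, dtype=float)
        self.grid_size = tuple(int(n) for n in self.grid_size)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != self.grid_size + (3,):
            raise UsageError("coefficient lattice shape must be grid_size + (3,)")
        if self.domain_origin is not None:
            self.domain_origin = np.asarray(self.domain_origin, dtype=float)
            self.domain_extent = np.asarray(self.domain_extent, dtype=float)

    # -- support geometry ---------------------------------------------------
    def _local_coords(self, points: np.ndarray, check: bool = True):
        u = (np.atleast_2d(points) - self.grid_origin) / self.grid_spacing
        n = np.asarray(self.grid_size)
        if check:
            # valid evaluation needs the full 4-point support in-lattice
            bad = (u < 1.0 - 1e-9) | (u > n - 2.0 + 1e-9)
            if bad.any():
                raise DomainError("point outside B-spline grid support")
        i = np.floor(u).astype(int)
        i = np.clip(i, 1, n - 3)
        t = u - i
        return i, t

    def support_weights(self, points: np.ndarray):
        """Flat lattice indices and weights of the 4x4x4 support per point.

        Returns (idx, w): idx int array (npts, 64) of flattened lattice
        indices, w (npts, 64) tensor-product basis weights.
        """
        i, t = self._local_coords(points)
        wx = bspline3_weights(t[:, 0])
        wy = bspline3_weights(t[:, 1])
        wz = bspline3_weights(t[:, 2])
        offs = np.arange(-1, 3)
        nx, ny, nz = self.grid_size
        ix = i[:, 0, None] + offs
        iy = i[:, 1, None] + offs
        iz = i[:, 2, None] + offs
        idx = (ix[:, :, None, None] * ny * nz
               + iy[:, None, :, None] * nz
               + iz[:, None, None, :]).reshape(-1, 64)
        w = (wx[:, :, None, None] * wy[:, None, :, None]
             * wz[:, None, None, :]).reshape(-1, 64)
        return idx, w

    def sparse_basis(self, points: np.ndarray) -> sparse.csr_matrix:
        """Sparse (npts x ncoef) basis matrix B with D(points) = B @ C."""
        idx, w = self.support_weights(points)
        npts = idx.shape[0]
        ncoef = int(np.prod(self.grid_size))
        indptr = np.arange(npts + 1) * 64
        return sparse.csr_matrix((w.ravel(), idx.ravel(), indptr),
                                 shape=(npts, ncoef))

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """Evaluate D at physical points (npts, 3) -> (npts, 3) mm."""
        idx, w = self.support_weights(points)
        flat = self.coefficients.reshape(-1, 3)
        return np.einsum("pk,pkc->pc", w, flat[idx])

    @property
    def n_parameters(self) -> int:
        return self.coefficients.size

    @classmethod
    def zero(cls, grid_origin, grid_spacing, grid_size,
             domain_origin=None, domain_extent=None) -> "BSplineTransform":
        grid_size = tuple(int(n) for n in grid_size)
        return cls(grid_origin=grid_origin, grid_spacing=grid_spacing,
                   grid_size=grid_size,
                   coefficients=np.zeros(grid_size + (3,)),
                   domain_origin=domain_origin, domain_extent=domain_extent)


def bspline_displacement(bspline: BSplineTransform, point) -> np.ndarray:
    """Displacement of a single physical point under the FFD (mm)."""
    return bspline.displacement(np.atleast_2d(point))[0]


def init_bspline_grid(fixed, spacing_mm: float) -> BSplineTransform:
    """Zero-coefficient control grid covering the fixed-image domain.

    The actual control spacing per axis is the largest value <= the request
    giving an integer number of intervals across the axis extent; one extra
    control point is added on each side for the cubic support margin.
    """
    if np.isscalar(spacing_mm):
        spacing_mm = np.full(3, float(spacing_mm))
    spacing_mm = np.asarray(spacing_mm, dtype=float)
    if np.any(spacing_mm <= 0):
        raise UsageError("grid spacing must be positive")
    extent = fixed.extent
    if np.any(extent < spacing_mm * 0.5):
        raise DegenerateInputError("image extent smaller than one grid interval")
    n_int = np.maximum(np.ceil(extent / spacing_mm - 1e-9).astype(int), 1)
    spacing = extent / n_int
    # domain origin: lower edge of voxel (0,0,0)
    domain_origin = fixed.origin - 0.5 * fixed.spacing
    grid_origin = domain_origin - spacing
    grid_size = tuple(n_int + 3)
    return BSplineTransform.zero(grid_origin, spacing, grid_size,
                                 domain_origin=domain_origin,
                                 domain_extent=extent)


def refine_bspline_grid(bspline: BSplineTransform, new_spacing_mm: float,
                        fixed=None, max_coefficients: int = 2_000_000,
                        rng=None) -> BSplineTransform:
    """Refit the displacement field on a finer control lattice.

    A dense grid of sample points across the domain is evaluated under the
    input field and the new lattice coefficients are found by least squares
    (lsmr); for dyadic spacing halvings this reproduces the field to
    round-off, and in general to well under 0.05 mm for smooth fields.
    """
    if np.isscalar(new_spacing_mm):
        new_spacing_mm = np.full(3, float(new_spacing_mm))
    new_spacing_mm = np.asarray(new_spacing_mm, dtype=float)
    if np.all(new_spacing_mm >= bspline.grid_spacing - 1e-9):
        raise UsageError("refinement requires a strictly smaller spacing")
    # an axis whose current spacing is already finer than the request keeps it
    new_spacing_mm = np.minimum(new_spacing_mm, bspline.grid_spacing)
    if bspline.domain_origin is None:
        raise UsageError("transform lacks domain information; cannot refine")
    extent = bspline.domain_extent
    n_int = np.maximum(np.ceil(extent / new_spacing_mm - 1e-9).astype(int), 1)
    spacing = extent / n_int
    grid_size = tuple(n_int + 3)
    if int(np.prod(grid_size)) * 3 > max_coefficients:
        raise MemoryError("refined B-spline grid exceeds the memory bound")
    out = BSplineTransform.zero(bspline.domain_origin - spacing, spacing,
                                grid_size, domain_origin=bspline.domain_origin,
                                domain_extent=extent)
    # sample points: 3 per new interval per axis, covering the domain
    axes = [np.linspace(0.0, extent[a], 3 * n_int[a] + 1) + bspline.domain_origin[a]
            for a in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    # clamp marginally inside both supports
    hi = bspline.domain_origin + extent
    pts = np.clip(pts, bspline.domain_origin + 1e-9, hi - 1e-9)
    target = bspline.displacement(pts)
    B = out.sparse_basis(pts)
    normal = (B.T @ B).tocsc()
    rhs = B.T @ target
    solve = factorized(normal)
    coef = np.column_stack([solve(rhs[:, c]) for c in range(3)])
    out.coefficients = coef.reshape(out.grid_size + (3,))
    return out


# ---------------------------------------------------------------------------
# Composite transform
# ---------------------------------------------------------------------------

@dataclass
class CompositeTransform:
    """T(p) = Rigid(p) + D(p); with a zero/absent FFD, T is the rigid motion."""

    rigid: RigidTransform
    bspline: BSplineTransform | None = None

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = self.rigid.transform_points(points)
        if self.bspline is not None:
            out = out + self.bspline.displacement(points)
        return out

    def transform_point(self, point) -> np.ndarray:
        return self.transform_points(np.atleast_2d(point))[0]


def transform_point(transform, point) -> np.ndarray:
    """Map one physical point (mm) through a rigid or composite transform."""
    if isinstance(transform, CompositeTransform):
        return transform.transform_point(point)
    return np.asarray(transform.transform_points(np.atleast_2d(point)))[0]


def dense_displacement_field(transform, geometry) -> np.ndarray:
    """Per-voxel displacement T(p) - p on an image grid, shape (*shape, 3) mm."""
    shape = geometry.shape
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    pts = geometry.origin + pts * geometry.spacing
    out = np.empty_like(pts)
    chunk = 500_000
    for s in range(0, len(pts), chunk):
        sl = slice(s, s + chunk)
        out[sl] = transform.transform_points(pts[sl]) - pts[sl]
    return out.reshape(shape + (3,))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_transform(transform: CompositeTransform, path) -> None:
    """Serialize a composite transform to JSON (coefficients row-major x,y,z)."""
    doc = {
        "rigid": {
            "rotation_rad": transform.rigid.rotation.tolist(),
            "translation_mm": transform.rigid.translation.tolist(),
            "center_mm": transform.rigid.center.tolist(),
        }
    }
    b = transform.bspline
    if b is not None:
        doc["bspline"] = {
            "grid_origin_mm": b.grid_origin.tolist(),
            "grid_spacing_mm": b.grid_spacing.tolist(),
            "grid_size": list(b.grid_size),
            "axis_order": "x,y,z (row-major over grid, innermost z; last axis = displacement component)",
            "coefficients_mm": b.coefficients.ravel().tolist(),
            "domain_origin_mm": None if b.domain_origin is None else b.domain_origin.tolist(),
            "domain_extent_mm": None if b.domain_extent is None else b.domain_extent.tolist(),
        }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_transform(path) -> CompositeTransform:
    with open(path) as fh:
        doc = json.load(fh)
    rigid = RigidTransform(rotation=doc["rigid"]["rotation_rad"],
                           translation=doc["rigid"]["translation_mm"],
                           center=doc["rigid"]["center_mm"])
    bspline = None
    if "bspline" in doc:
        b = doc["bspline"]
        size = tuple(b["grid_size"])
        coef = np.asarray(b["coefficients_mm"]).reshape(size + (3,))
        bspline = BSplineTransform(
            grid_origin=b["grid_origin_mm"], grid_spacing=b["grid_spacing_mm"],
            grid_size=size, coefficients=coef,
            domain_origin=b["domain_origin_mm"], domain_extent=b["domain_extent_mm"])
    return CompositeTransform(rigid=rigid, bspline=bspline)
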