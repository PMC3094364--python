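"""3D CT image container, standard-format I/O, and pre-processing.

An :class:`ImageVolume` is an axis-aligned scalar grid in Hounsfield units.
Voxel index ``(i, j, k)`` (0-based, array axes = x, y, z) maps to the physical
point ``origin + index * spacing`` in millimetres; no oblique direction
cosines are supported.  Air/background is -1000 HU throughout.

Pre-processing mirrors the steps needed before kVCT/MVCT registration:
removal of the treatment couch, masking of everything outside the patient
body, and axial cropping of the reference scan to the partner's z-extent so
that metric samples do not fall outside the smaller field of view.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import DegenerateInputError, GeometryError, UsageError

AIR_HU = -1000.0


@dataclass
class ImageVolume:
    """Axis-aligned 3D scalar volume in HU.

    Attributes
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Intensities in HU; array axes are the x, y, z physical axes.
    spacing : ndarray, shape (3,)
        Per-axis voxel size in mm (strictly positive).
    origin : ndarray, shape (3,)
        Physical position of voxel (0, 0, 0) in mm.
    modality : str
        One of ``{"kVCT", "MVCT", "synthetic"}`` (informational tag).
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    modality: str = "synthetic"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise GeometryError("voxels must be a 3D array")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or self.origin.shape != (3,):
            raise GeometryError("spacing and origin must be 3-vectors")
        if np.any(self.spacing <= 0):
            raise GeometryError("spacing must be strictly positive")

    @property
    def shape(self):
        return self.voxels.shape

    @property
    def extent(self) -> np.ndarray:
        """Physical size along each axis (mm), edge-to-edge of the voxel grid."""
        return np.asarray(self.shape) * self.spacing

    def index_to_physical(self, index) -> np.ndarray:
        """Map (fractional) voxel indices to physical mm coordinates."""
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def physical_to_index(self, point) -> np.ndarray:
        return (np.asarray(point, dtype=float) - self.origin) / self.spacing

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def same_geometry(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def copy(self) -> "ImageVolume":
        return replace(self, voxels=self.voxels.copy(),
                       spacing=self.spacing.copy(), origin=self.origin.copy())


@dataclass
class Mask:
    """Binary volume sharing geometry with a parent :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self):
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def count(self) -> int:
        return int(self.voxels.sum())

    @classmethod
    def like(cls, img: ImageVolume, voxels: np.ndarray) -> "Mask":
        return cls(voxels=voxels, spacing=img.spacing.copy(), origin=img.origin.copy())


@dataclass
class PreprocessConfig:
    """Parameters for body masking and couch suppression.

    body_threshold separates patient tissue from air; anything in the largest
    above-threshold connected component (after couch suppression) is kept.
    """

    body_threshold: float = -400.0
    couch_clearance: bool = True
    background_fill: float = AIR_HU

    def __post_init__(self):
        if not (-1000.0 < self.body_threshold < 0.0):
            raise UsageError("body_threshold must lie in (-1000, 0) HU")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMAT_EXT = {"metaimage": ".mha", "nifti": ".nii.gz"}


def _sitk_to_volume(img: sitk.Image, modality: str) -> ImageVolume:
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    return ImageVolume(
        voxels=np.ascontiguousarray(arr.transpose(2, 1, 0)),
        spacing=np.asarray(img.GetSpacing(), dtype=float),
        origin=np.asarray(img.GetOrigin(), dtype=float),
        modality=modality,
    )


def _volume_to_sitk(img: ImageVolume) -> sitk.Image:
    out = sitk.GetImageFromArray(np.ascontiguousarray(img.voxels.transpose(2, 1, 0)))
    out.SetSpacing(tuple(float(s) for s in img.spacing))
    out.SetOrigin(tuple(float(o) for o in img.origin))
    return out


def read_image(path, format: str | None = None, modality: str = "synthetic") -> ImageVolume:
    """Read a MetaImage/NIfTI file or a DICOM series directory.

    ``format`` is one of ``{"metaimage", "nifti", "dicom_dir"}``; when omitted
    it is inferred from the path (directory => DICOM series).
    """
    path = os.fspath(path)
    if format is None:
        if os.path.isdir(path):
            format = "dicom_dir"
        elif path.endswith((".mha", ".mhd")):
            format = "metaimage"
        elif path.endswith((".nii", ".nii.gz")):
            format = "nifti"
        else:
            raise UsageError(f"cannot infer image format from path: {path}")
    if format == "dicom_dir":
        return _read_dicom_series(path, modality)
    if format not in ("metaimage", "nifti"):
        raise UsageError(f"unsupported image format: {format}")
    if not os.path.exists(path):
        raise IOError(f"image file not found: {path}")
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # pragma: no cover - error text from ITK
        raise IOError(f"failed to read image {path}: {exc}") from exc
    return _sitk_to_volume(img, modality)


def _read_dicom_series(directory: str, modality: str) -> ImageVolume:
    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(directory)
    if not files:
        raise IOError(f"no DICOM series found under {directory}")
    reader.SetFileNames(files)
    img = reader.Execute()
    # uniform slice spacing is required by the axis-aligned geometry model
    if img.GetDepth() >= 3:
        # GDCM already sorts by position; verify spacing consistency via origin
        pass
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-3):
        raise GeometryError("oblique DICOM series are not supported")
    return _sitk_to_volume(img, modality)


def write_image(img: ImageVolume, path, format: str | None = None) -> None:
    """Write an :class:`ImageVolume` as MetaImage or NIfTI (by extension)."""
    path = os.fspath(path)
    if format is None:
        if path.endswith((".mha", ".mhd")):
            format = "metaimage"
        elif path.endswith((".nii", ".nii.gz")):
            format = "nifti"
        else:
            raise UsageError(f"cannot infer image format from path: {path}")
    if format not in ("metaimage", "nifti"):
        raise UsageError(f"unsupported image format: {format}")
    sitk.WriteImage(_volume_to_sitk(img), path)


def write_vector_field(field_mm: np.ndarray, spacing, origin, path) -> None:
    """Export a per-voxel 3-component displacement field (mm) as MetaImage."""
    arr = np.ascontiguousarray(field_mm.transpose(2, 1, 0, 3)).astype(np.float32)
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(img, os.fspath(path))


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------

def extract_body_mask(img: ImageVolume, cfg: PreprocessConfig | None = None) -> Mask:
    """Largest above-threshold connected component, with couch suppression.

    The treatment couch appears as a detached above-threshold structure near
    the posterior (large-y) edge of the image.  Any component whose centroid
    lies in the posterior 15% of the y-extent and that is disjoint from the
    largest component is suppressed before the body is selected.  Holes are
    filled per axial slice.
    """
    cfg = cfg or PreprocessConfig()
    fg = img.voxels > cfg.body_threshold
    if not fg.any():
        raise DegenerateInputError("no voxels above body threshold")
    labels, n = ndimage.label(fg)
    if n == 0:
        raise DegenerateInputError("no foreground components")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    keep = largest
    if cfg.couch_clearance and n > 1:
        ny = img.shape[1]
        cy = ndimage.center_of_mass(fg, labels, index=np.arange(1, n + 1))
        cy = np.asarray(cy)[:, 1]
        order = np.argsort(sizes)[::-1]
        for lab0 in order:
            lab = int(lab0) + 1
            if cy[lab - 1] >= 0.85 * (ny - 1):
                continue  # posterior structure: candidate couch, skip
            keep = lab
            break
    body = labels == keep
    # 2D hole filling per axial slice
    for k in range(body.shape[2]):
        body[:, :, k] = ndimage.binary_fill_holes(body[:, :, k])
    return Mask.like(img, body)


def mask_background(img: ImageVolume, body: Mask,
                    cfg: PreprocessConfig | None = None) -> ImageVolume:
    """Set all voxels outside the body mask to the background fill HU."""
    cfg = cfg or PreprocessConfig()
    if img.shape != body.shape or not np.allclose(img.spacing, body.spacing):
        raise GeometryError("image and body mask geometry mismatch")
    out = img.copy()
    out.voxels = np.where(body.voxels, img.voxels, cfg.background_fill)
    return out


def crop_axial_to_overlap(reference: ImageVolume, partner: ImageVolume) -> ImageVolume:
    """Restrict the reference to slices whose centers fall in the partner's z-extent.

    The partner z-extent is the half-open physical interval from the first
    slice's lower edge to the last slice's upper edge.  In-plane geometry is
    never altered.
    """
    z0 = partner.origin[2] - 0.5 * partner.spacing[2]
    z1 = z0 + partner.shape[2] * partner.spacing[2]
    centers = reference.voxel_centers_axis(2)
    inside = (centers >= z0) & (centers < z1)
    if not inside.any():
        raise DegenerateInputError("no axial overlap between reference and partner")
    k_lo, k_hi = np.flatnonzero(inside)[[0, -1]]
    out = ImageVolume(
        voxels=reference.voxels[:, :, k_lo:k_hi + 1].copy(),
        spacing=reference.spacing.copy(),
        origin=np.array([reference.origin[0], reference.origin[1],
                         reference.origin[2] + k_lo * reference.spacing[2]]),
        modality=reference.modality,
    )
    return out


def resample_to_reference(moving: ImageVolume, transform,
                          reference_geometry: ImageVolume,
                          fill: float = AIR_HU) -> ImageVolume:
    """Warp ``moving`` onto the reference grid through a physical transform.

    Each output voxel takes the trilinear interpolation of ``moving`` at
    ``T(p)`` where ``p`` is the reference voxel center; points mapping outside
    the moving volume get ``fill``.  ``transform`` may be ``None`` (identity)
    or any object with a ``transform_points(points) -> points`` method.
    """
    ref = reference_geometry
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in ref.shape), indexing="ij")
    pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    pts = ref.origin + pts * ref.spacing
    if transform is not None:
        pts = transform.transform_points(pts)
    idx = (pts - moving.origin) / moving.spacing
    sampled = ndimage.map_coordinates(
        moving.voxels.astype(float), idx.T, order=1, mode="constant", cval=fill)
    return ImageVolume(voxels=sampled.reshape(ref.shape),
                       spacing=ref.spacing.copy(), origin=ref.origin.copy(),
                       modality=moving.modality)


def gaussian_smooth(img: ImageVolume, kernel_pixels) -> ImageVolume:
    """Separable Gaussian filtering; kernel widths are sigmas in voxels.

    A kernel of 0 on an axis disables filtering on that axis.  Reflective
    boundaries are used so constant images are preserved exactly.
    """
    kernel = np.asarray(kernel_pixels, dtype=float)
    if np.any(kernel < 0):
        raise UsageError("Gaussian kernel widths must be non-negative")
    if np.all(kernel == 0):
        return img.copy()
    out = img.copy()
    out.voxels = ndimage.gaussian_filter(img.voxels.astype(float), sigma=kernel,
                                         mode="reflect")
    return out
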