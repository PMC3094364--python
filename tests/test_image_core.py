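"""Image container, I/O round-trips and pre-processing operations."""

import numpy as np
import pytest

from tomoreg.errors import DegenerateInputError, GeometryError, UsageError
from tomoreg.image import (ImageVolume, Mask, PreprocessConfig,
                           crop_axial_to_overlap, extract_body_mask,
                           gaussian_smooth, mask_background, read_image,
                           resample_to_reference, write_image)


def _random_volume(rng, shape=(10, 10, 5), spacing=(1.0, 1.0, 4.0)):
    return ImageVolume(rng.uniform(-1000, 1000, shape).astype(np.float64),
                       spacing=spacing, origin=(1.0, -2.0, 3.0))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ext", [".mha", ".nii.gz", ".nii"])
def test_write_read_roundtrip_is_lossless(tmp_path, ext):
    rng = np.random.default_rng(0)
    vol = _random_volume(rng)
    path = tmp_path / f"vol{ext}"
    write_image(vol, path)
    back = read_image(path)
    np.testing.assert_allclose(back.voxels, vol.voxels)
    np.testing.assert_allclose(back.spacing, vol.spacing)
    np.testing.assert_allclose(back.origin, vol.origin)


def test_metaimage_header_echo(tmp_path):
    vol = ImageVolume(np.zeros((10, 10, 5)), spacing=(1, 1, 4))
    path = tmp_path / "v.mha"
    write_image(vol, path)
    assert tuple(read_image(path).spacing) == (1.0, 1.0, 4.0)


def test_nifti_cross_read_against_nibabel(tmp_path):
    """A NIfTI written by an independent library must read identically."""
    nib = pytest.importorskip("nibabel")
    rng = np.random.default_rng(1)
    data = rng.uniform(-1000, 500, (12, 11, 7))
    affine = np.diag([1.5, 2.0, 3.0, 1.0])
    affine[:3, 3] = (4.0, 5.0, 6.0)
    path = tmp_path / "ref.nii.gz"
    nib.save(nib.Nifti1Image(data, affine), path)
    vol = read_image(path)
    np.testing.assert_allclose(vol.voxels, data, atol=1e-5)
    np.testing.assert_allclose(vol.spacing, (1.5, 2.0, 3.0))


def test_compressed_and_uncompressed_nifti_agree(tmp_path):
    rng = np.random.default_rng(2)
    vol = _random_volume(rng)
    write_image(vol, tmp_path / "a.nii")
    write_image(vol, tmp_path / "a.nii.gz")
    np.testing.assert_allclose(read_image(tmp_path / "a.nii").voxels,
                               read_image(tmp_path / "a.nii.gz").voxels)


def test_unsupported_format_is_a_usage_error(tmp_path):
    vol = ImageVolume(np.zeros((4, 4, 4)), spacing=(1, 1, 1))
    with pytest.raises(UsageError):
        write_image(vol, tmp_path / "v.xyz")
    with pytest.raises(IOError):
        read_image(tmp_path / "missing.mha")


# ---------------------------------------------------------------------------
# Body masking and couch suppression
# ---------------------------------------------------------------------------

def _ellipsoid_image(shape=(40, 40, 16), spacing=(2.0, 2.0, 3.0),
                     semi=(30.0, 26.0, 20.0), couch=False):
    img = ImageVolume(np.full(shape, -1000.0), spacing=spacing)
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    X, Y, Z = (g * s for g, s in zip((ii, jj, kk), spacing))
    c = 0.5 * (np.asarray(shape) - 1) * np.asarray(spacing)
    member = (((X - c[0]) / semi[0]) ** 2 + ((Y - c[1]) / semi[1]) ** 2
              + ((Z - c[2]) / semi[2]) ** 2) <= 1.0
    img.voxels[member] = 40.0
    if couch:
        img.voxels[8:32, -4:-2, :] = 200.0
    return img, member


def test_body_mask_matches_analytic_ellipsoid():
    img, member = _ellipsoid_image()
    mask = extract_body_mask(img)
    from scipy import ndimage
    dil = ndimage.binary_dilation(member)
    ero = ndimage.binary_erosion(member)
    assert np.all(mask.voxels[ero])           # covers the eroded ellipsoid
    assert not np.any(mask.voxels & ~dil)     # within one-voxel band


def test_body_mask_on_all_air_image_raises():
    img = ImageVolume(np.full((8, 8, 4), -1000.0), spacing=(1, 1, 1))
    with pytest.raises(DegenerateInputError):
        extract_body_mask(img)


def test_couch_slab_is_suppressed():
    img, member = _ellipsoid_image(couch=True)
    mask = extract_body_mask(img)
    assert not np.any(mask.voxels[:, -4:, :])
    assert np.any(mask.voxels)


def test_mask_background_fills_couch_and_is_idempotent():
    img, member = _ellipsoid_image(couch=True)
    body = extract_body_mask(img)
    out = mask_background(img, body)
    assert np.all(out.voxels[8:32, -4:-2, :] == -1000.0)
    twice = mask_background(out, body)
    np.testing.assert_array_equal(twice.voxels, out.voxels)
    full = Mask.like(img, np.ones(img.shape, bool))
    np.testing.assert_array_equal(mask_background(img, full).voxels, img.voxels)


def test_mask_background_geometry_mismatch():
    img, _ = _ellipsoid_image()
    bad = Mask(np.ones((4, 4, 4)), spacing=img.spacing)
    with pytest.raises(GeometryError):
        mask_background(img, bad)


# ---------------------------------------------------------------------------
# Axial cropping
# ---------------------------------------------------------------------------

def test_crop_superset_partner_returns_reference_unchanged():
    ref = ImageVolume(np.arange(4 * 4 * 10, dtype=float).reshape(4, 4, 10),
                      spacing=(1, 1, 3.27))
    partner = ImageVolume(np.zeros((4, 4, 40)), spacing=(1, 1, 4),
                          origin=(0, 0, -50))
    out = crop_axial_to_overlap(ref, partner)
    np.testing.assert_array_equal(out.voxels, ref.voxels)


def test_crop_slice_center_rule():
    # 90 slices at 3.27 mm; partner covers physical z in [0, 80):
    # slices with center k*3.27 < 80 are kept -> k = 0..24, 25 slices
    ref = ImageVolume(np.zeros((4, 4, 90)), spacing=(1, 1, 3.27))
    partner = ImageVolume(np.zeros((4, 4, 20)), spacing=(1, 1, 4),
                          origin=(0, 0, 2.0))  # edges [0, 80)
    out = crop_axial_to_overlap(ref, partner)
    centers = np.arange(90) * 3.27
    assert out.shape[2] == int(np.sum((centers >= 0) & (centers < 80)))
    assert out.shape[:2] == ref.shape[:2]
    np.testing.assert_allclose(out.spacing, ref.spacing)


def test_crop_disjoint_extents_raise():
    ref = ImageVolume(np.zeros((4, 4, 10)), spacing=(1, 1, 3))
    partner = ImageVolume(np.zeros((4, 4, 5)), spacing=(1, 1, 4),
                          origin=(0, 0, 100))
    with pytest.raises(DegenerateInputError):
        crop_axial_to_overlap(ref, partner)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def test_resample_identity_is_exact():
    rng = np.random.default_rng(3)
    vol = _random_volume(rng)
    out = resample_to_reference(vol, None, vol)
    np.testing.assert_allclose(out.voxels, vol.voxels)


class _Shift:
    def __init__(self, t):
        self.t = np.asarray(t, dtype=float)

    def transform_points(self, pts):
        return pts + self.t


def test_resample_one_voxel_translation_matches_integer_shift():
    rng = np.random.default_rng(4)
    vol = _random_volume(rng, shape=(12, 10, 8), spacing=(1, 1, 4))
    out = resample_to_reference(vol, _Shift((1.0, 0, 0)), vol)
    # T(p) = p + dx: output voxel i samples moving at i+1
    np.testing.assert_allclose(out.voxels[:-1], vol.voxels[1:])
    assert np.all(out.voxels[-1] == -1000.0)  # fill enters one face


def test_resample_half_voxel_on_linear_ramp():
    shape = (16, 6, 6)
    ramp = np.broadcast_to(np.arange(16, dtype=float)[:, None, None] * 10.0,
                           shape).copy()
    vol = ImageVolume(ramp, spacing=(2.0, 2.0, 2.0))
    out = resample_to_reference(vol, _Shift((1.0, 0, 0)), vol)  # half voxel
    expected = ramp + 5.0
    np.testing.assert_allclose(out.voxels[:-1], expected[:-1])


# ---------------------------------------------------------------------------
# Gaussian smoothing
# ---------------------------------------------------------------------------

def test_gaussian_zero_kernel_is_identity_and_constants_preserved():
    rng = np.random.default_rng(5)
    vol = _random_volume(rng)
    np.testing.assert_array_equal(gaussian_smooth(vol, (0, 0, 0)).voxels,
                                  vol.voxels)
    const = ImageVolume(np.full((10, 10, 10), 123.0), spacing=(1, 1, 1))
    np.testing.assert_allclose(gaussian_smooth(const, (3, 2, 1)).voxels, 123.0,
                               rtol=1e-12)


def test_gaussian_delta_matches_dense_convolution_oracle():
    vol = ImageVolume(np.zeros((21, 21, 21)), spacing=(1, 1, 1))
    vol.voxels[10, 10, 10] = 1.0
    out = gaussian_smooth(vol, (2, 2, 2)).voxels
    # dense separable oracle with the same truncation as scipy (4 sigma)
    r = int(4 * 2)
    x = np.arange(-r, r + 1)
    k = np.exp(-x ** 2 / (2 * 4.0))
    k /= k.sum()
    oracle = np.einsum("i,j,k->ijk", k, k, k)
    sub = out[10 - r:10 + r + 1, 10 - r:10 + r + 1, 10 - r:10 + r + 1]
    np.testing.assert_allclose(sub, oracle, atol=1e-10)


def test_gaussian_negative_kernel_rejected():
    vol = ImageVolume(np.zeros((4, 4, 4)), spacing=(1, 1, 1))
    with pytest.raises(UsageError):
        gaussian_smooth(vol, (-1, 0, 0))


def test_preprocess_config_threshold_contract():
    with pytest.raises(UsageError):
        PreprocessConfig(body_threshold=100.0)
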