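"""CC, TRE, lung segmentation, correspondence indices, Wilcoxon, cohorts."""

import itertools

import numpy as np
import pytest
from scipy import ndimage

from tomoreg.errors import (DegenerateInputError, GeometryError, UsageError)
from tomoreg.image import ImageVolume, Mask
from tomoreg.reference_cohort import (PATIENT1_LEFT_LUNG_CM3,
                                      reference_sessions)
from tomoreg.transforms import CompositeTransform, RigidTransform
from tomoreg.validation import (LandmarkSet, LungMask, aggregate_cohort,
                                centroid_error, correlation_coefficient,
                                jaccard_index, lung_volume,
                                restrict_to_common_extent,
                                segment_lungs_region_growing,
                                split_left_right, target_registration_error,
                                transform_landmarks, volume_error,
                                wilcoxon_signed_rank)


def _mask(vox, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return Mask(np.asarray(vox, bool), spacing, origin)


# ---------------------------------------------------------------------------
# Correlation coefficient
# ---------------------------------------------------------------------------

class TestCorrelationCoefficient:
    def _pair(self, seed=0, shape=(70, 70, 10)):
        rng = np.random.default_rng(seed)
        a = ImageVolume(rng.uniform(-1000, 500, shape), spacing=(1, 1, 3))
        return a

    def test_identical_images_give_one(self):
        a = self._pair()
        assert correlation_coefficient(a, a) == pytest.approx(1.0)

    def test_linear_intensity_relation_gives_one(self):
        a = self._pair(1)
        b = a.copy()
        b.voxels = 2.0 * a.voxels + 100.0
        assert correlation_coefficient(a, b) == pytest.approx(1.0)

    def test_affine_rescale_invariance(self):
        a = self._pair(2)
        b = self._pair(3)
        cc = correlation_coefficient(a, b)
        b2 = b.copy()
        b2.voxels = 3.5 * b.voxels - 50.0
        assert correlation_coefficient(a, b2) == pytest.approx(cc, abs=1e-12)

    def test_small_interior_matches_direct_formula(self):
        # 64x64x5 with border 30/2 leaves a 4x4x1 interior
        x = np.arange(16, dtype=float).reshape(4, 4)
        y = np.array([[2.0, 5, 3, 8], [1, 9, 4, 7],
                      [6, 2, 8, 3], [5, 5, 1, 9]])
        a = ImageVolume(np.zeros((64, 64, 5)), spacing=(1, 1, 1))
        b = ImageVolume(np.zeros((64, 64, 5)), spacing=(1, 1, 1))
        a.voxels[30:34, 30:34, 2] = x
        b.voxels[30:34, 30:34, 2] = y
        xm, ym = x.mean(), y.mean()
        direct = (((x - xm) * (y - ym)).sum()
                  / np.sqrt(((x - xm) ** 2).sum() * ((y - ym) ** 2).sum()))
        assert correlation_coefficient(a, b) == pytest.approx(direct,
                                                              abs=1e-12)

    def test_border_exclusion_ignores_border_content(self):
        a = self._pair(4)
        b = a.copy()
        b.voxels = a.voxels.copy()
        b.voxels[:30] = 999.0     # inside the stripped x border
        b.voxels[:, :, :2] = -999.0
        assert correlation_coefficient(a, b) == pytest.approx(1.0)

    def test_constant_interior_raises(self):
        a = self._pair(5)
        b = a.copy()
        b.voxels = np.zeros_like(a.voxels)
        with pytest.raises(DegenerateInputError):
            correlation_coefficient(a, b)
        small = ImageVolume(np.zeros((10, 10, 3)), spacing=(1, 1, 1))
        with pytest.raises(DegenerateInputError):
            correlation_coefficient(small, small)


# ---------------------------------------------------------------------------
# Landmarks and TRE
# ---------------------------------------------------------------------------

class TestLandmarks:
    def test_identity_and_translation(self):
        marks = LandmarkSet({"a": (1, 2, 3), "b": (4, 5, 6)})
        ident = CompositeTransform(rigid=RigidTransform())
        np.testing.assert_allclose(
            transform_landmarks(marks, ident).points(["a", "b"]),
            marks.points(["a", "b"]))
        shift = CompositeTransform(rigid=RigidTransform(translation=(1, 1, 1)))
        np.testing.assert_allclose(
            transform_landmarks(marks, shift).entries["a"], (2, 3, 4))

    def test_out_of_domain_goes_to_exclusion_report(self):
        from tomoreg.transforms import init_bspline_grid
        img = ImageVolume(np.zeros((10, 10, 10)), spacing=(2, 2, 2))
        T = CompositeTransform(rigid=RigidTransform(),
                               bspline=init_bspline_grid(img, 10.0))
        marks = LandmarkSet({"in": (5, 5, 5), "out": (500, 0, 0)})
        exclusions = []
        mapped = transform_landmarks(marks, T, exclusions)
        assert "in" in mapped.entries and "out" not in mapped.entries
        assert exclusions and exclusions[0]["label"] == "out"

    def test_csv_roundtrip(self, tmp_path):
        marks = LandmarkSet({"carina": (1.5, -2.0, 3.25)})
        path = tmp_path / "marks.csv"
        marks.write_csv(path)
        back = LandmarkSet.read_csv(path)
        np.testing.assert_allclose(back.entries["carina"], (1.5, -2.0, 3.25))

    def test_tre_zero_and_pythagorean(self):
        a = LandmarkSet({"p": (0, 0, 0)})
        b = LandmarkSet({"p": (3, 4, 0)}, frame="MVCT")
        per, summ = target_registration_error(a, a)
        assert per["p"] == 0.0
        per, summ = target_registration_error(a, b)
        assert per["p"] == pytest.approx(5.0)
        assert summ["max"] == pytest.approx(5.0)

    def test_tre_mean_of_session_means_matches_reported_value(self):
        # patient-1 elastic session means: 2.42, 4.18, 4.11 -> 3.57
        assert round(np.mean([2.42, 4.18, 4.11]), 2) == 3.57

    def test_tre_summary_invariants(self):
        rng = np.random.default_rng(0)
        pts = {f"m{i}": rng.uniform(0, 50, 3) for i in range(8)}
        ref = {k: v + rng.uniform(-5, 5, 3) for k, v in pts.items()}
        per, summ = target_registration_error(
            LandmarkSet(pts), LandmarkSet(ref, frame="MVCT"))
        assert summ["max"] >= summ["mean"] >= 0
        worst = max(per, key=per.get)
        sub = {k: v for k, v in pts.items() if k != worst}
        _, summ2 = target_registration_error(
            LandmarkSet(sub), LandmarkSet(ref, frame="MVCT"))
        assert summ2["mean"] <= summ["mean"] + 1e-12

    def test_no_common_labels_is_an_error(self):
        with pytest.raises(UsageError):
            target_registration_error(LandmarkSet({"a": (0, 0, 0)}),
                                      LandmarkSet({"b": (0, 0, 0)}))


# ---------------------------------------------------------------------------
# Lung segmentation and splitting
# ---------------------------------------------------------------------------

class TestSegmentation:
    def test_phantom_lungs_recovered(self, phantom_pair):
        img, truth = phantom_pair
        mask = segment_lungs_region_growing(img)
        true = truth.lung_masks_fixed["left"].voxels \
            | truth.lung_masks_fixed["right"].voxels
        overlap = (mask.voxels & true).sum()
        assert overlap >= 0.99 * true.sum()
        dilated = ndimage.binary_dilation(true)
        assert not np.any(mask.voxels & ~dilated)

    def test_exterior_air_is_never_labeled(self, phantom_pair):
        img, _ = phantom_pair
        from tomoreg.image import extract_body_mask
        body = extract_body_mask(img)
        mask = segment_lungs_region_growing(img, body=body)
        assert not np.any(mask.voxels & ~body.voxels)

    def test_body_without_lung_range_voxels_raises(self):
        img = ImageVolume(np.full((20, 20, 6), -1000.0), spacing=(2, 2, 2))
        img.voxels[5:15, 5:15, :] = 0.0  # body only
        with pytest.raises(DegenerateInputError):
            segment_lungs_region_growing(img)

    def test_split_two_ellipsoids_exactly(self, phantom_pair):
        img, truth = phantom_pair
        both = truth.lung_masks_fixed["left"].voxels \
            | truth.lung_masks_fixed["right"].voxels
        left, right = split_left_right(
            Mask(both, img.spacing, img.origin))
        np.testing.assert_array_equal(left.mask.voxels,
                                      truth.lung_masks_fixed["left"].voxels)
        np.testing.assert_array_equal(right.mask.voxels,
                                      truth.lung_masks_fixed["right"].voxels)
        assert left.side == "left" and right.side == "right"

    def test_fused_lungs_split_by_midsagittal_plane(self):
        vox = np.zeros((40, 20, 10), bool)
        vox[5:35, 5:15, 2:8] = True  # one fused slab across the midline
        left, right = split_left_right(_mask(vox))
        assert not np.any(left.mask.voxels & right.mask.voxels)
        lv, rv = left.mask.count(), right.mask.count()
        assert abs(lv - rv) / max(lv, rv) < 0.05
        assert ndimage.center_of_mass(left.mask.voxels)[0] > \
            ndimage.center_of_mass(right.mask.voxels)[0]

    def test_empty_mask_raises(self):
        with pytest.raises(DegenerateInputError):
            split_left_right(_mask(np.zeros((4, 4, 4))))


class TestCommonExtent:
    def _lung(self, z0=0.0):
        vox = np.zeros((10, 10, 20), bool)
        vox[2:8, 2:8, :] = True
        return LungMask(side="left", mask=_mask(vox, (1, 1, 2), (0, 0, z0)))

    def test_identical_fov_unchanged(self):
        a, b = self._lung(), self._lung()
        ra, rb = restrict_to_common_extent(a, b, (-10, 100))
        np.testing.assert_array_equal(ra.mask.voxels, a.mask.voxels)

    def test_half_fov_halves_a_uniform_slab(self):
        a, b = self._lung(), self._lung()
        full = lung_volume(a)
        ra, _ = restrict_to_common_extent(a, b, (0, 20.0))  # half of 40 mm
        assert abs(lung_volume(ra) - 0.5 * full) <= 6 * 6 * 2  # one slice
    def test_disjoint_fov_raises(self):
        a, b = self._lung(), self._lung()
        with pytest.raises(DegenerateInputError):
            restrict_to_common_extent(a, b, (100, 200))


# ---------------------------------------------------------------------------
# Correspondence indices
# ---------------------------------------------------------------------------

class TestIndices:
    def test_lung_volume_arithmetic(self):
        vox = np.zeros((20, 20, 10), bool)
        vox.ravel()[:1000] = True
        assert lung_volume(_mask(vox, (1, 1, 4))) == pytest.approx(4000.0)
        assert lung_volume(_mask(np.zeros((4, 4, 4)))) == 0.0

    def test_ellipsoid_volume_close_to_analytic(self, phantom_pair):
        img, truth = phantom_pair
        a, b, c = 24.0, 34.0, 64.0
        # z semi-axis truncated by the image: integrate the truncated ellipsoid
        zmax = min(c, img.extent[2] / 2)
        u = zmax / c
        analytic = np.pi * a * b * c * (2 * u - 2 * u ** 3 / 3)
        vol = lung_volume(truth.lung_masks_fixed["left"])
        assert vol == pytest.approx(analytic, rel=0.02)

    def test_volume_error_formula_and_reported_cells(self):
        assert volume_error(1000.0, 1000.0) == 0.0
        v = PATIENT1_LEFT_LUNG_CM3
        assert round(volume_error(v["kvct"], v["rigid_mvct"]), 2) == 24.85
        assert round(volume_error(v["kvct"], v["elastic_mvct"]), 2) == 1.97
        with pytest.raises(UsageError):
            volume_error(0.0, 1.0)

    def test_centroid_error_cases(self):
        vox = np.zeros((20, 20, 10), bool)
        vox[4:9, 6:12, 3:7] = True
        m = _mask(vox, (0.2, 0.2, 1.0))
        assert centroid_error(m, m) == 0.0
        shifted = _mask(np.roll(vox, (3, 4, 0), axis=(0, 1, 2)),
                        (0.2, 0.2, 1.0))
        # integer-voxel shift (3, 4, 0) at 0.2 mm -> (0.6, 0.8, 0) -> 1.0 mm
        assert centroid_error(m, shifted) == pytest.approx(1.0, abs=1e-9)
        with pytest.raises(DegenerateInputError):
            centroid_error(m, _mask(np.zeros_like(vox)))

    def test_centroid_error_is_a_metric(self):
        rng = np.random.default_rng(0)
        masks = []
        for _ in range(3):
            vox = np.zeros((16, 16, 8), bool)
            vox[tuple(rng.integers(2, (14, 14, 6)))] = True
            vox[tuple(rng.integers(2, (14, 14, 6)))] = True
            masks.append(_mask(vox))
        a, b, c = masks
        assert centroid_error(a, b) == pytest.approx(centroid_error(b, a))
        assert centroid_error(a, c) <= centroid_error(a, b) \
            + centroid_error(b, c) + 1e-12

    def test_jaccard_cases(self):
        base = np.zeros((30, 10, 10), bool)
        a = base.copy()
        a.ravel()[:100] = True
        assert jaccard_index(_mask(a), _mask(a)) == 1.0
        b = base.copy()
        b.ravel()[100:200] = True
        assert jaccard_index(_mask(a), _mask(b)) == 0.0
        c = base.copy()
        c.ravel()[50:150] = True
        assert jaccard_index(_mask(a), _mask(c)) == pytest.approx(1 / 3)
        assert jaccard_index(_mask(c), _mask(a)) == pytest.approx(1 / 3)
        with pytest.raises(DegenerateInputError):
            jaccard_index(_mask(base), _mask(base))
        with pytest.raises(GeometryError):
            jaccard_index(_mask(a), _mask(np.zeros((4, 4, 4))))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _brute_force_p(d):
    """Exact two-sided p by enumerating every sign assignment."""
    from scipy.stats import rankdata
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([0, 1], repeat=n)]
    ws = np.asarray(ws, float)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_uniform_shift_n15_hits_the_extreme_tail(self):
        rigid = np.arange(1.0, 16.0)
        elastic = rigid - 1.0  # uniformly better
        p = wilcoxon_signed_rank(rigid, elastic)
        assert p == pytest.approx(2.0 / 2 ** 15, rel=1e-12)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            d = np.round(rng.normal(0.3, 1.0, 6), 2)
            d = d[d != 0]
            if len(d) == 0:
                continue
            p = wilcoxon_signed_rank(d, np.zeros_like(d))
            assert p == pytest.approx(_brute_force_p(d), abs=1e-12)

    def test_matches_brute_force_with_ties(self):
        d = np.array([1.0, 1.0, -1.0, 2.0, 2.0, 3.0])
        p = wilcoxon_signed_rank(d, np.zeros_like(d))
        assert p == pytest.approx(_brute_force_p(d), abs=1e-12)

    def test_matches_scipy_exact_for_tie_free_data(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon
        rng = np.random.default_rng(2)
        x = rng.normal(5, 1, 12)
        y = x + rng.normal(0.4, 0.7, 12)
        expected = scipy_wilcoxon(x, y, mode="exact").pvalue
        assert wilcoxon_signed_rank(x, y) == pytest.approx(expected,
                                                           rel=1e-10)

    def test_antisymmetric_differences_sit_at_the_null_center(self):
        d = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0, 4.0, -4.0])
        p = wilcoxon_signed_rank(d, np.zeros_like(d))
        assert p == pytest.approx(1.0)

    def test_all_zero_differences_raise(self):
        with pytest.raises(DegenerateInputError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# Cohort aggregation over the bundled reference sessions
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def table():
    return aggregate_cohort(reference_sessions())


class TestCohortAggregation:

    def test_cc_means(self, table):
        assert round(table.aggregates["cc_rigid"]["mean"], 2) == 0.93
        assert round(table.aggregates["cc_elastic"]["mean"], 2) == 0.98

    def test_patient1_elastic_tre(self, table):
        p1 = table.aggregates["tre_elastic_per_patient"]["1"]
        assert round(p1["mean"], 2) == 3.57
        assert round(p1["sd"], 2) == 1.00

    def test_pooled_centroid_errors(self, table):
        assert round(table.aggregates["ce_rigid"]["mean"], 2) == 3.03
        assert round(table.aggregates["ce_elastic"]["mean"], 2) == 0.87

    def test_pooled_absolute_volume_error(self, table):
        assert table.aggregates["abs_ve_rigid"]["mean"] == \
            pytest.approx(8.22, abs=0.0051)

    def test_wilcoxon_flags_every_metric_as_improved(self, table):
        for key in ("cc", "abs_ve", "ce", "jac"):
            assert table.wilcoxon_p[key] < 0.01

    def test_aggregate_is_recomputable_from_rows(self, table):
        df = table.rows
        assert np.isclose(df["cc_elastic"].mean(),
                          table.aggregates["cc_elastic"]["mean"])
        pooled = np.abs(np.concatenate([df["ve_left_rigid"],
                                        df["ve_right_rigid"]]))
        assert np.isclose(pooled.mean(),
                          table.aggregates["abs_ve_rigid"]["mean"])
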