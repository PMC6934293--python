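"""Coil density, gliding-box lacunarity, standardized-distance comparison."""

import itertools

import numpy as np
import pytest
from scipy import stats

from coildeploy.section_metrics import (
    BinaryImage,
    CoilDistribution,
    SectionPlane,
    aneurysm_average,
    coil_density,
    compare_groups,
    distance_summary,
    euclidean_distance,
    extract_sections,
    lacunarity,
    rasterize,
    standardize,
)


def image(pixels, mask=None):
    pixels = np.asarray(pixels, dtype=bool)
    if mask is None:
        mask = np.ones_like(pixels, dtype=bool)
    return BinaryImage(pixels=pixels, resolution=0.05, mask=np.asarray(mask, dtype=bool))


def brute_force_lacunarity(binary, r):
    """Exhaustive gliding-box Λ(r) by explicit window enumeration."""
    h, w = binary.shape
    masses = [
        binary[i : i + r, j : j + r].sum()
        for i in range(h - r + 1)
        for j in range(w - r + 1)
    ]
    masses = np.asarray(masses, dtype=float)
    mu = masses.mean()
    if mu == 0:
        return 1.0
    return masses.var() / mu**2 + 1.0


class TestCoilDensity:
    def test_extremes_and_fraction(self):
        assert coil_density(image(np.zeros((10, 10)))) == 0.0
        assert coil_density(image(np.ones((10, 10)))) == 1.0
        px = np.zeros((10, 10), dtype=bool)
        px[:5, :5] = True
        assert coil_density(image(px)) == pytest.approx(0.25)

    def test_mask_restricts_denominator(self):
        px = np.zeros((10, 10), dtype=bool)
        px[0, 0] = True
        mask = np.zeros((10, 10), dtype=bool)
        mask[:2, :2] = True
        assert coil_density(image(px, mask)) == pytest.approx(0.25)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            coil_density(image(np.zeros((4, 4)), np.zeros((4, 4))))


class TestLacunarity:
    def test_single_corner_pixel_4x4_r2(self):
        # a corner pixel is covered by exactly one of the nine sliding 2x2
        # windows: masses {1 once, 0 x8} -> Λ = 8/(1/9) /9 ... = 9
        px = np.zeros((4, 4), dtype=bool)
        px[0, 0] = True
        assert lacunarity(image(px), box_sizes=[2]) == pytest.approx(9.0)

    def test_single_interior_pixel_4x4_r2(self):
        # an interior pixel lies in four windows: masses {1 x4, 0 x5}
        px = np.zeros((4, 4), dtype=bool)
        px[1, 1] = True
        assert lacunarity(image(px), box_sizes=[2]) == pytest.approx(2.25)

    def test_uniform_fill_has_unit_lacunarity(self):
        assert lacunarity(image(np.ones((8, 8))), box_sizes=[2, 4]) == pytest.approx(1.0)

    def test_clustered_exceeds_dispersed_at_equal_density(self):
        clustered = np.zeros((8, 8), dtype=bool)
        clustered[3:5, 3:5] = True
        dispersed = np.zeros((8, 8), dtype=bool)
        dispersed[1, 1] = dispersed[1, 6] = dispersed[6, 1] = dispersed[6, 6] = True
        lc = lacunarity(image(clustered), box_sizes=[2])
        ld = lacunarity(image(dispersed), box_sizes=[2])
        assert lc > ld

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(12)
        for size in (4, 5, 6, 8):
            for _ in range(40):
                px = rng.random((size, size)) < 0.35
                if px.sum() == 0:
                    continue
                for r in (1, 2, 4):
                    if r > size:
                        continue
                    got = lacunarity(image(px), box_sizes=[r])
                    assert got == pytest.approx(brute_force_lacunarity(px, r), abs=1e-12)

    def test_matches_brute_force_exhaustive_3x3(self):
        for bits in itertools.product([0, 1], repeat=9):
            px = np.array(bits, dtype=bool).reshape(3, 3)
            if px.sum() == 0:
                continue
            got = lacunarity(image(px), box_sizes=[2])
            assert got == pytest.approx(brute_force_lacunarity(px, 2), abs=1e-12)

    def test_empty_image_is_one_by_convention(self):
        with pytest.warns(UserWarning, match="convention"):
            assert lacunarity(image(np.zeros((6, 6)))) == 1.0

    def test_at_least_one_always(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            px = rng.random((12, 12)) < rng.uniform(0.05, 0.9)
            if px.sum() == 0:
                continue
            assert lacunarity(image(px)) >= 1.0

    def test_oversized_box_skipped_with_warning(self):
        px = np.zeros((4, 4), dtype=bool)
        px[0, 0] = True
        with pytest.warns(UserWarning, match="skipped"):
            val = lacunarity(image(px), box_sizes=[2, 64])
        assert val == pytest.approx(9.0)


class TestAveragesAndStandardization:
    def test_aneurysm_average(self):
        rows = [CoilDistribution(cd=c, lac=l) for c, l in
                zip([0.1, 0.2, 0.3, 0.4, 0.5], [2, 2, 2, 2, 2])]
        cd, lac = aneurysm_average(rows)
        assert cd == pytest.approx(0.3)
        assert lac == pytest.approx(2.0)
        rows2 = list(reversed(rows))
        assert aneurysm_average(rows2) == (cd, lac)

    def test_standardize_mean_zero_sd_one(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(20, 2)) * [3.0, 0.1] + [5.0, 40.0]
        z = standardize(pts)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0), 1.0, atol=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 2))
        assert np.allclose(standardize(pts), standardize(pts * 7.5 + 3.0))

    def test_two_points_map_to_plus_minus_one(self):
        z = standardize(np.array([[0.0, 10.0], [1.0, 20.0]]))
        assert np.allclose(np.abs(z), 1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            standardize(np.array([[1.0, 2.0], [1.0, 3.0]]))


class TestDistances:
    def test_identity_symmetry_and_345(self):
        assert euclidean_distance((1, 1), (1, 1)) == 0.0
        assert euclidean_distance((0, 0), (3, 4)) == pytest.approx(5.0)
        assert euclidean_distance((2, 7), (-1, 3)) == euclidean_distance((-1, 3), (2, 7))

    def test_summary_hand_enumerated_centroid_case(self):
        # dAvg uses the centroid, so it can undercut dMin
        d_min, d_max, d_avg = distance_summary((1.0, 0.0), [(0.0, 0.0), (2.0, 0.0)])
        assert (d_min, d_max, d_avg) == (1.0, 1.0, 0.0)

    def test_single_virtual_point_collapses(self):
        d_min, d_max, d_avg = distance_summary((0.0, 0.0), [(3.0, 4.0)])
        assert d_min == d_max == d_avg == pytest.approx(5.0)

    def test_coincident_points_give_zero(self):
        assert distance_summary((2.0, 2.0), [(2.0, 2.0)] * 9) == (0.0, 0.0, 0.0)

    def test_min_never_exceeds_max(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            pts = rng.normal(size=(9, 2))
            d_min, d_max, d_avg = distance_summary(rng.normal(size=2), pts)
            assert d_min <= d_max
            assert d_avg <= d_max + 1e-12


class TestCompareGroups:
    def test_identical_groups(self):
        rep = compare_groups([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert rep["t_stat"] == 0.0
        assert rep["p_value"] == pytest.approx(1.0)
        assert rep["mean_a"] == rep["mean_b"]

    def test_clearly_separated_groups(self):
        rep = compare_groups([0.0, 0.0, 0.0, 0.1], [10.0, 10.0, 10.0, 10.1])
        # closed-form pooled two-sample t cross-check
        t_ref = stats.ttest_ind([0.0, 0.0, 0.0, 0.1], [10.0, 10.0, 10.0, 10.1],
                                equal_var=True)
        assert rep["p_value"] < 1e-3
        assert rep["t_stat"] == pytest.approx(t_ref.statistic)
        assert rep["significant"]

    def test_small_groups_skip_normality(self):
        with pytest.warns(UserWarning, match="normality"):
            rep = compare_groups([1.0, 2.0], [1.5, 2.5])
        assert "shapiro_a_p" not in rep

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0])


class TestSections:
    def test_plane_spacing_and_orientation(self, sidewall_case):
        planes = extract_sections(sidewall_case, n=3, spacing=1.0)
        for a, b in zip(planes, planes[1:]):
            assert np.linalg.norm(b.origin - a.origin) == pytest.approx(1.0)
            assert np.allclose(a.normal, b.normal)
        apex = sidewall_case.dome_apex()
        neck = sidewall_case.orifice_contour.mean(axis=0)
        axis = (neck - apex) / np.linalg.norm(neck - apex)
        assert np.allclose(planes[0].normal, axis)

    def test_too_many_planes_reports_feasible_count(self, sidewall_case):
        with pytest.raises(ValueError, match="at most"):
            extract_sections(sidewall_case, n=40, spacing=1.0)

    def test_perpendicular_segment_rasterizes_to_disc(self, sidewall_case):
        d2 = 0.2921
        planes = extract_sections(sidewall_case, n=3, spacing=1.0)
        plane = planes[1]
        seg = np.vstack([plane.origin - plane.normal, plane.origin + plane.normal])
        img = rasterize([seg], plane, sidewall_case, d2, resolution=d2 / 8.0)
        area = img.pixels.sum() * img.resolution**2
        assert area == pytest.approx(np.pi * d2**2 / 4.0, rel=0.05)

    def test_oblique_slab_larger_than_disc(self, sidewall_case):
        d2 = 0.2921
        plane = extract_sections(sidewall_case, n=3, spacing=1.0)[1]
        u = np.array([1.0, 0.0, 0.0])
        u = u - (u @ plane.normal) * plane.normal
        u /= np.linalg.norm(u)
        seg = np.vstack([plane.origin - 1.2 * u, plane.origin + 1.2 * u])
        img = rasterize([seg], plane, sidewall_case, d2, resolution=d2 / 8.0)
        assert img.pixels.sum() * img.resolution**2 > np.pi * d2**2 / 4.0

    def test_empty_configuration_all_white(self, sidewall_case):
        plane = extract_sections(sidewall_case, n=3, spacing=1.0)[0]
        img = rasterize([], plane, sidewall_case, 0.2921)
        assert img.pixels.sum() == 0

    def test_resolution_guard(self, sidewall_case):
        plane = extract_sections(sidewall_case, n=3, spacing=1.0)[0]
        with pytest.raises(ValueError, match="resolution"):
            rasterize([], plane, sidewall_case, 0.2921, resolution=0.2)

    def test_mask_is_single_connected_disc(self, sidewall_case):
        from scipy import ndimage

        plane = extract_sections(sidewall_case, n=3, spacing=1.0)[0]
        img = rasterize([], plane, sidewall_case, 0.2921)
        _, n_components = ndimage.label(img.mask)
        assert n_components == 1
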