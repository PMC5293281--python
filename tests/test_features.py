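import itertools
import math

import numpy as np
import pytest

from dceradiomics import (
    DceCase,
    GlcmSpec,
    Volume,
    bilateral_difference,
    bpe_features,
    bpe_select,
    compute_enhancement_maps,
    extract_features,
    first_order_features,
    generate_case,
    glcm3d_features,
    morphologic_features,
    tumor_dynamic_features,
)
from dceradiomics.core_io import BreastMask, PipelineConfig, TumorMask
from dceradiomics.features import UNIT_OFFSETS_3D


def brute_first_order(vals):
    vals = np.asarray(vals, dtype=float)
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    sd = math.sqrt(var)
    if sd == 0:
        return (0.0, 0.0, max(vals), mean, 0.0)
    skew = sum((v - mean) ** 3 for v in vals) / n / sd**3
    kurt = sum((v - mean) ** 4 for v in vals) / n / sd**4
    return (skew, kurt, max(vals), mean, sd)


def brute_glcm(data, region, levels, offsets):
    """All-pair enumeration oracle for the 3D co-occurrence features."""
    vals = data[region]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q = np.minimum(((data - lo) / (hi - lo) * levels).astype(int), levels - 1)
    else:
        q = np.zeros(data.shape, dtype=int)
    counts = np.zeros((levels, levels))
    coords = list(zip(*np.nonzero(region)))
    region_set = set(coords)
    for (x, y, z) in coords:
        for (dx, dy, dz) in offsets:
            nb = (x + dx, y + dy, z + dz)
            if nb in region_set:
                counts[q[x, y, z], q[nb]] += 1
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        return (0.0, 0.0, 1.0, 1.0, 0.0)
    p = counts / total
    i = np.arange(levels)
    pi, pj = p.sum(1), p.sum(0)
    mu_i, mu_j = (i * pi).sum(), (i * pj).sum()
    sd_i = math.sqrt(((i - mu_i) ** 2 * pi).sum())
    sd_j = math.sqrt(((i - mu_j) ** 2 * pj).sum())
    contrast = sum(p[a, b] * (a - b) ** 2 for a in i for b in i)
    corr = (
        sum(p[a, b] * (a - mu_i) * (b - mu_j) for a in i for b in i) / (sd_i * sd_j)
        if sd_i > 0 and sd_j > 0
        else 0.0
    )
    energy = (p**2).sum()
    homog = sum(p[a, b] / (1 + abs(a - b)) for a in i for b in i)
    ent = -sum(p[a, b] * math.log2(p[a, b]) for a in i for b in i if p[a, b] > 0)
    return (contrast, corr, energy, homog, ent)


class TestEnhancementMaps:
    def _case(self, s0, s1, s2):
        return DceCase(
            case_id="t", series=(Volume(s0), Volume(s1), Volume(s2)),
            age=50, menopausal=1, subtype="HER2",
        )

    def test_printed_equation_example(self):
        s0 = np.full((2, 2, 2), 100.0)
        s1 = np.full((2, 2, 2), 150.0)
        maps = compute_enhancement_maps(self._case(s0, s1, s1))
        assert maps.sub10[0, 0, 0] == 50.0
        assert maps.rel1[0, 0, 0] == pytest.approx(0.5)

    def test_identical_series_give_zero_maps(self):
        s0 = np.random.default_rng(1).uniform(10, 100, (3, 3, 2))
        maps = compute_enhancement_maps(self._case(s0, s0.copy(), s0.copy()))
        assert np.all(maps.sub10 == 0) and np.all(maps.rel1 == 0)

    def test_matches_elementwise_oracle(self, rng):
        s0 = rng.uniform(1, 100, (4, 4, 2))
        s1 = rng.uniform(1, 100, (4, 4, 2))
        s2 = rng.uniform(1, 100, (4, 4, 2))
        maps = compute_enhancement_maps(self._case(s0, s1, s2), epsilon=0.5)
        for (x, y, z) in itertools.product(range(4), range(4), range(2)):
            assert maps.sub21[x, y, z] == s2[x, y, z] - s1[x, y, z]
            if s0[x, y, z] > 0.5:
                assert maps.rel2[x, y, z] == pytest.approx((s2[x, y, z] - s0[x, y, z]) / s0[x, y, z])


class TestFirstOrder:
    def test_constant_region_convention(self):
        out = first_order_features(np.full((3, 1, 1), 5.0), np.ones((3, 1, 1), dtype=bool))
        assert out == (0.0, 0.0, 5.0, 5.0, 0.0)

    def test_symmetric_values_have_zero_skewness(self):
        vol = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        out = first_order_features(vol, np.ones((3, 1, 1), dtype=bool))
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_moment_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 40))
            vals = rng.normal(10, 4, n)
            vol = vals.reshape(n, 1, 1)
            out = first_order_features(vol, np.ones((n, 1, 1), dtype=bool))
            np.testing.assert_allclose(out, brute_first_order(vals), atol=1e-10)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            first_order_features(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), dtype=bool))


def digital_ball(r, shape=None):
    n = 2 * r + 3
    x, y, z = np.ogrid[:n, :n, :n]
    c = n // 2
    return (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= r**2


class TestMorphologic:
    def test_single_voxel_volume(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        out = morphologic_features(m, (1.0, 1.0, 1.0))
        assert out[0] == pytest.approx(1.0)

    def test_ball_compactness_near_one_and_above_ellipsoid(self):
        ball = digital_ball(10)
        c_ball = morphologic_features(ball, (1.0, 1.0, 1.0))[4]
        n = 45
        x, y, z = np.ogrid[:n, :n, :n]
        c = n // 2
        # 4:1 elongated ellipsoid of similar volume (semi-axes 4a, a, a)
        a = (10.0**3 / 4.0) ** (1.0 / 3.0)
        ell = ((x - c) / (4 * a)) ** 2 + ((y - c) / a) ** 2 + ((z - c) / a) ** 2 <= 1.0
        c_ell = morphologic_features(ell, (1.0, 1.0, 1.0))[4]
        assert abs(c_ball - 1.0) < 0.15
        assert c_ball > c_ell

    def test_ball_radial_dispersion_small(self):
        ball = digital_ball(10)
        vol, diameter, radius_sd, roughness, _ = morphologic_features(ball, (1.0, 1.0, 1.0))
        mean_r = diameter / 2.0
        assert radius_sd / mean_r < 0.1
        assert roughness < 0.1

    def test_anisotropic_spacing_scales_volume(self):
        m = np.ones((2, 2, 2), dtype=bool)
        out = morphologic_features(m, (0.625, 0.625, 1.2))
        assert out[0] == pytest.approx(8 * 0.625 * 0.625 * 1.2)


class TestGlcm3d:
    def test_constant_region_degenerate_values(self):
        out = glcm3d_features(np.full((3, 3, 3), 7.0), np.ones((3, 3, 3), dtype=bool))
        assert out == (0.0, 0.0, 1.0, 1.0, 0.0)

    def test_checkerboard_hand_count(self):
        # 2x2x1 checkerboard, single offset (1,0,0): all co-occurrences are
        # between the two extreme levels -> mass fully off-diagonal
        data = np.array([[0.0, 1.0], [1.0, 0.0]]).reshape(2, 2, 1)
        spec = GlcmSpec(levels=2, offsets=((1, 0, 0),))
        contrast, corr, energy, homog, ent = glcm3d_features(data, np.ones((2, 2, 1), dtype=bool), spec)
        # hand count: pairs (0,0)-(1,0) and (0,1)-(1,1), both cross-level
        assert contrast == pytest.approx(1.0)  # (i-j)^2 = 1 for all mass
        assert energy == pytest.approx(0.5)
        assert homog == pytest.approx(0.5)
        assert ent == pytest.approx(1.0)

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(10):
            data = rng.uniform(0, 50, (5, 5, 3))
            region = rng.random((5, 5, 3)) < 0.8
            if region.sum() < 4:
                continue
            spec = GlcmSpec(levels=8)
            mine = glcm3d_features(data, region, spec)
            ref = brute_glcm(data, region, 8, UNIT_OFFSETS_3D + tuple((-a, -b, -c) for a, b, c in UNIT_OFFSETS_3D))
            np.testing.assert_allclose(mine, ref, atol=1e-8)

    def test_intensity_shift_invariance(self, rng):
        data = rng.uniform(0, 50, (6, 6, 3))
        region = np.ones((6, 6, 3), dtype=bool)
        a = glcm3d_features(data, region)
        b = glcm3d_features(data + 123.0, region)
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestTumorDynamic:
    def _maps(self, s0, s1, s2):
        case = DceCase(case_id="t", series=(Volume(s0), Volume(s1), Volume(s2)), age=40, menopausal=0, subtype="basal")
        return compute_enhancement_maps(case, epsilon=1e-9)

    def test_uniform_enhancement_ratio(self):
        s0 = np.full((2, 2, 2), 100.0)
        maps = self._maps(s0, s0 + 50.0, s0 + 80.0)
        out = tumor_dynamic_features(maps, np.ones((2, 2, 2), dtype=bool))
        assert out[0] == pytest.approx(50.0)  # sub10 mean
        assert out[9] == pytest.approx(1.6)  # (S2-S0)/(S1-S0)
        assert out[10] == pytest.approx(0.6)  # (S2-S1)/(S1-S0)

    def test_s2_equal_s1_zeroes_sub21(self):
        s0 = np.full((2, 2, 2), 100.0)
        s1 = s0 + 30.0
        maps = self._maps(s0, s1, s1.copy())
        out = tumor_dynamic_features(maps, np.ones((2, 2, 2), dtype=bool))
        assert out[6:9] == (0.0, 0.0, 0.0)
        assert out[10] == pytest.approx(0.0)

    def test_matches_per_voxel_oracle(self, rng):
        s0 = rng.uniform(50, 150, (3, 3, 2))
        s1 = rng.uniform(50, 250, (3, 3, 2))
        s2 = rng.uniform(50, 250, (3, 3, 2))
        mask = rng.random((3, 3, 2)) < 0.7
        mask.flat[0] = True
        maps = self._maps(s0, s1, s2)
        out = tumor_dynamic_features(maps, mask, ratio_epsilon=1e-9)
        expect = []
        for sub in (s1 - s0, s2 - s0, s2 - s1):
            v = sub[mask]
            expect += [v.mean(), v.std(), v.max()]
        d = (s1 - s0)[mask]
        expect += [((s2 - s0)[mask] / d).mean(), ((s2 - s1)[mask] / d).mean()]
        np.testing.assert_allclose(out, expect, atol=1e-10)


class TestBpe:
    def _setup(self, rng, n=10):
        shape = (n, 4, 2)
        left = np.zeros(shape, dtype=bool)
        left[: n // 2] = True
        right = ~left
        s0 = rng.uniform(50, 100, shape)
        s1 = s0 * rng.uniform(1.0, 1.5, shape)
        s2 = s0 * rng.uniform(1.0, 1.8, shape)
        tumor = np.zeros(shape, dtype=bool)
        tumor[0, 0, 0] = True
        case = DceCase(
            case_id="b", series=(Volume(s0), Volume(s1), Volume(s2)), age=55, menopausal=1,
            subtype="HER2",
            breast_mask=BreastMask(left=left, right=right, laterality_of_lesion="left"),
            tumor_mask=TumorMask(mask=tumor, seed=(0, 0, 0)),
        )
        return case, compute_enhancement_maps(case, epsilon=1e-9)

    def test_top_percent_count_and_argmax(self, rng):
        case, maps = self._setup(rng, n=50)
        region = bpe_select(maps, case.breast_mask, case.tumor_mask, "lesion", p=1.0)
        eligible = case.breast_mask.lesion_side & ~case.tumor_mask.mask
        assert region.count == math.ceil(0.01 * eligible.sum())
        # the selected voxels are the rel1-argmax set by brute-force sort
        rel = maps.rel1[eligible]
        top = np.sort(rel)[::-1][: region.count]
        np.testing.assert_allclose(np.sort(maps.rel1[region.voxels]), np.sort(top))

    def test_all_equal_rel_uses_index_order(self):
        shape = (6, 2, 1)
        left = np.zeros(shape, dtype=bool)
        left[:3] = True
        s0 = np.full(shape, 100.0)
        case = DceCase(
            case_id="tie", series=(Volume(s0), Volume(s0 * 1.2), Volume(s0 * 1.3)),
            age=40, menopausal=0, subtype="basal",
            breast_mask=BreastMask(left=left, right=~left, laterality_of_lesion="left"),
            tumor_mask=TumorMask(mask=np.eye(1, 12, 0, dtype=bool).reshape(shape), seed=(0, 0, 0)),
        )
        maps = compute_enhancement_maps(case, epsilon=1e-9)
        region = bpe_select(maps, case.breast_mask, case.tumor_mask, "lesion", p=40.0)
        flat = np.ravel_multi_index(region.voxels, shape)
        eligible_flat = np.flatnonzero((left & ~case.tumor_mask.mask).ravel())
        np.testing.assert_array_equal(np.sort(flat), eligible_flat[: region.count])

    def test_distinct_values_brute_force_sort(self, rng):
        case, maps = self._setup(rng, n=250)
        region = bpe_select(maps, case.breast_mask, case.tumor_mask, "contralateral", p=1.0)
        eligible = case.breast_mask.contralateral_side
        rel_sorted = np.sort(maps.rel1[eligible])[::-1]
        k = region.count
        assert np.sort(maps.rel1[region.voxels])[::-1] == pytest.approx(rel_sorted[:k])

    def test_dynamic_block_matches_direct_recomputation(self, rng):
        case, maps = self._setup(rng)
        lesion = bpe_select(maps, case.breast_mask, case.tumor_mask, "lesion", p=10.0)
        contra = bpe_select(maps, case.breast_mask, case.tumor_mask, "contralateral", p=10.0)
        texture, dynamic = bpe_features(case, maps, lesion, contra)
        assert len(texture) == 15 and len(dynamic) == 18
        expect = []
        for region in (lesion, contra):
            for sub in (maps.sub10, maps.sub20, maps.sub21):
                v = sub[region.voxels]
                expect += [v.mean(), v.std(), v.max()]
        np.testing.assert_allclose(dynamic, expect, atol=1e-10)

    def test_bilateral_antisymmetry_and_zero(self, rng):
        vals = tuple(rng.normal(size=18))
        d = bilateral_difference(vals)
        swapped = bilateral_difference(vals[9:] + vals[:9])
        np.testing.assert_allclose(np.array(d), -np.array(swapped), atol=1e-12)
        assert bilateral_difference(vals[:9] + vals[:9]) == pytest.approx((0.0,) * 9)

    def test_bilateral_simple_arithmetic(self):
        vals = (30.0,) + (0.0,) * 8 + (10.0,) + (0.0,) * 8
        assert bilateral_difference(vals)[0] == pytest.approx(20.0)


class TestExtractFeatures:
    def test_full_vector_on_synthetic_case(self, aligned_case):
        case, _ = aligned_case
        vec = extract_features(case)
        assert vec.values.shape == (90,)
        assert np.all(np.isfinite(vec.values))
        assert vec[1] == case.age
        assert vec[2] == case.menopausal

    def test_deterministic(self, aligned_case):
        case, _ = aligned_case
        v1 = extract_features(case)
        v2 = extract_features(case)
        np.testing.assert_array_equal(v1.values, v2.values)

    def test_static_series_zero_dynamics(self, aligned_case):
        case, _ = aligned_case
        static = DceCase(
            case_id="static", series=(case.s0, case.s0, case.s0), age=case.age,
            menopausal=case.menopausal, subtype=case.subtype,
            breast_mask=case.breast_mask, tumor_mask=case.tumor_mask,
        )
        vec = extract_features(static)
        # all subtraction-derived features (38-48, 64-90) vanish
        assert all(vec[i] == 0.0 for i in range(38, 49))
        assert all(vec[i] == 0.0 for i in range(64, 91))

    def test_intensity_shift_moves_only_location_features(self, aligned_case):
        case, _ = aligned_case
        shift = 100.0
        shifted = DceCase(
            case_id="shift",
            series=tuple(Volume(v.data + shift, v.spacing) for v in case.series),
            age=case.age, menopausal=case.menopausal, subtype=case.subtype,
            breast_mask=case.breast_mask, tumor_mask=case.tumor_mask,
        )
        a = extract_features(case)
        # relative-enhancement ranking changes under an intensity shift, so
        # pin the BPE regions by comparing only tumor-block features
        b = extract_features(shifted)
        for img in range(3):
            base = 3 + 5 * img
            assert b[base] == pytest.approx(a[base], abs=1e-8)  # skewness
            assert b[base + 1] == pytest.approx(a[base + 1], abs=1e-8)  # kurtosis
            assert b[base + 2] == pytest.approx(a[base + 2] + shift)  # max
            assert b[base + 3] == pytest.approx(a[base + 3] + shift)  # mean
            assert b[base + 4] == pytest.approx(a[base + 4], abs=1e-8)  # sd
        for i in range(23, 38):  # tumor GLCM: min-max quantization
            assert b[i] == pytest.approx(a[i], abs=1e-8)
        for i in range(38, 49):  # subtraction maps cancel the shift
            assert b[i] == pytest.approx(a[i], abs=1e-8)
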