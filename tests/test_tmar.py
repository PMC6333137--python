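"""Modified SSIM, artifact splitting, fusion and the MAR pipelines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tiltmar.recon import ReconImage
from tiltmar.tmar import (ArtifactMap, PipelineParams, SSIMParams,
                          artifact_split, atmar_pipeline, correlation_maps,
                          denoise, fuse, modified_ssim_map, tmar_pipeline)


def img(a, px=0.1, **kw):
    return ReconImage(np.asarray(a, dtype=float), px, **kw)


def brute_force_ssim(x, y, c2, c3, include_luminance=False, c1=None):
    """Scalar contrast*structure evaluation on two full patches."""
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    sx, sy = np.sqrt(vx), np.sqrt(vy)
    c = (2 * sx * sy + c2) / (vx + vy + c2)
    s = (cov + c3) / (sx * sy + c3)
    val = c * s
    if include_luminance:
        val *= (2 * mx * my + c1) / (mx * mx + my * my + c1)
    return val


class TestModifiedSSIM:
    def test_self_similarity_is_one(self, rng):
        x = rng.random((16, 16))
        m = modified_ssim_map(x, x.copy())
        assert m.values == pytest.approx(1.0, abs=1e-9)

    def test_anticorrelation_limit(self, rng):
        x = rng.standard_normal((32, 32))  # zero-mean, variance >> c3
        p = SSIMParams(c2=1e-6, c3=5e-7, dynamic_range=1.0)
        m = modified_ssim_map(x, -x, p)
        assert np.median(m.values) == pytest.approx(-1.0, abs=1e-4)

    def test_center_matches_brute_force_patch(self, rng):
        """Map center equals the scalar formula on the extracted 5x5 patch."""
        x = rng.random((11, 11))
        y = rng.random((11, 11))
        p = SSIMParams(c2=1e-4, c3=5e-5, dynamic_range=1.0)
        m = modified_ssim_map(x, y, p)
        expected = brute_force_ssim(x[3:8, 3:8], y[3:8, 3:8], 1e-4, 5e-5)
        assert m.values[5, 5] == pytest.approx(expected, abs=1e-10)

    def test_oracle_equivalence_on_200_random_patches(self, rng):
        """Sliding map values equal per-patch brute force, 200 samples."""
        x = rng.standard_normal((40, 40))
        y = rng.standard_normal((40, 40))
        p = SSIMParams(c2=2e-3, c3=1e-3, dynamic_range=1.0)
        m = modified_ssim_map(x, y, p).values
        worst = 0.0
        for _ in range(200):
            i = rng.integers(2, 38)
            j = rng.integers(2, 38)
            bf = brute_force_ssim(x[i - 2:i + 3, j - 2:j + 3],
                                  y[i - 2:i + 3, j - 2:j + 3], 2e-3, 1e-3)
            worst = max(worst, abs(m[i, j] - bf))
        assert worst < 1e-10

    @given(arrays(np.float64, (12, 12), elements=st.floats(-1, 1)),
           arrays(np.float64, (12, 12), elements=st.floats(-1, 1)))
    @settings(max_examples=30, deadline=None)
    def test_bounded_by_one(self, x, y):
        m = modified_ssim_map(x, y, SSIMParams(dynamic_range=2.0))
        assert np.abs(m.values).max() <= 1.0 + 1e-9

    def test_even_patch_rejected(self):
        with pytest.raises(ValueError):
            SSIMParams(patch=4)

    def test_patch_larger_than_image_rejected(self, rng):
        with pytest.raises(ValueError, match="patch"):
            modified_ssim_map(rng.random((3, 3)), rng.random((3, 3)),
                              SSIMParams(patch=5))


class TestDenoise:
    def test_sigma_zero_identity(self, rng):
        a = img(rng.random((8, 8)))
        assert denoise(a, 0.0) is a

    def test_constant_image_unchanged(self):
        a = img(np.full((16, 16), 3.3))
        assert denoise(a, 2.0).values == pytest.approx(3.3, abs=1e-12)

    def test_impulse_center_weight_matches_gaussian(self):
        n = 33
        a = np.zeros((n, n))
        a[n // 2, n // 2] = 1.0
        out = denoise(img(a), 1.0).values
        k = np.arange(n) - n // 2
        g = np.exp(-k ** 2 / 2.0)
        g /= g.sum()
        assert out[n // 2, n // 2] == pytest.approx(g[n // 2] ** 2, abs=1e-6)


class TestArtifactSplit:
    def test_identical_inputs_zero_map(self, rng):
        a = img(rng.random((8, 8)))
        assert not artifact_split(a, a).values.any()

    def test_constant_offset(self, rng):
        v = rng.random((8, 8))
        m = artifact_split(img(v + 0.5), img(v))
        assert m.values == pytest.approx(0.5, abs=1e-12)

    def test_antisymmetry(self, rng):
        a, b = img(rng.random((8, 8))), img(rng.random((8, 8)))
        assert np.array_equal(artifact_split(a, b).values,
                              -artifact_split(b, a).values)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            artifact_split(img(rng.random((8, 8))), img(rng.random((9, 9))))


class TestCorrelationMaps:
    def test_streak_in_ordinary_scan_raises_c_ori(self, rng):
        base = np.full((32, 32), 0.2) + 0.002 * rng.standard_normal((32, 32))
        streak = np.zeros((32, 32))
        streak[14:18, :] = 0.05
        ori, tilt = img(base + streak), img(base.copy())
        art = artifact_split(ori, tilt)
        c_ori, c_tilt = correlation_maps(ori, tilt, art)
        band = np.s_[13:19, 8:24]
        assert np.median(c_ori.values[band]) > np.median(c_tilt.values[band])

    def test_swap_symmetry(self, rng):
        """Swapping which input is 'ordinary' swaps the two maps."""
        a = img(rng.random((16, 16)))
        b = img(rng.random((16, 16)))
        c_ori, c_tilt = correlation_maps(a, b, artifact_split(a, b))
        d_ori, d_tilt = correlation_maps(b, a, artifact_split(b, a))
        assert np.array_equal(c_ori.values, d_tilt.values)
        assert np.array_equal(c_tilt.values, d_ori.values)

    def test_zero_artifact_map_both_defined_and_equal(self, rng):
        a = img(rng.random((16, 16)))
        c1, c2 = correlation_maps(a, img(a.values.copy()),
                                  ArtifactMap(np.zeros((16, 16))))
        assert np.array_equal(c1.values, c2.values)

    def test_inconsistent_artifact_map_rejected(self, rng):
        a, b = img(rng.random((8, 8))), img(rng.random((8, 8)))
        bad = ArtifactMap(a.values - b.values + 1.0)
        with pytest.raises(ValueError, match="difference"):
            correlation_maps(a, b, bad)


class TestFuse:
    def _maps(self, c_ori, c_tilt):
        from tiltmar.tmar import CorrelationMap

        return CorrelationMap(c_ori, 5), CorrelationMap(c_tilt, 5)

    def test_all_ordinary_limit(self, rng):
        a, b = img(rng.random((8, 8))), img(rng.random((8, 8)))
        lo, hi = self._maps(np.zeros((8, 8)), np.ones((8, 8)))
        res = fuse(a, b, lo, hi)
        assert np.array_equal(res.fused.values, a.values)

    def test_tie_takes_tilted(self, rng):
        a, b = img(rng.random((8, 8))), img(rng.random((8, 8)))
        same, same2 = self._maps(np.full((8, 8), 0.3), np.full((8, 8), 0.3))
        res = fuse(a, b, same, same2)
        assert np.array_equal(res.fused.values, b.values)

    def test_checkerboard_membership(self, rng):
        a, b = img(rng.random((8, 8))), img(rng.random((8, 8)))
        board = np.indices((8, 8)).sum(axis=0) % 2 == 0
        c_ori = np.where(board, 0.0, 1.0)
        res = fuse(a, b, *self._maps(c_ori, np.full((8, 8), 0.5)))
        assert np.array_equal(res.fused.values,
                              np.where(board, a.values, b.values))

    @given(arrays(np.float64, (6, 6), elements=st.floats(-1, 1)),
           arrays(np.float64, (6, 6), elements=st.floats(-1, 1)))
    @settings(max_examples=30, deadline=None)
    def test_membership_property(self, c_o, c_t):
        rng = np.random.default_rng(0)
        a, b = img(rng.random((6, 6))), img(rng.random((6, 6)))
        res = fuse(a, b, *self._maps(c_o, c_t))
        member = (res.fused.values == a.values) | (res.fused.values == b.values)
        assert member.all()
        # ties must resolve to the tilted input
        ties = c_o == c_t
        assert np.array_equal(res.fused.values[ties], b.values[ties])


class TestPipelines:
    def test_identical_pair_returns_tilted_and_zero_mape(self, rng):
        v = 0.2 + 0.01 * rng.standard_normal((32, 32))
        a, b = img(v), img(v.copy())
        res = tmar_pipeline(a, b, PipelineParams(metal_threshold=None,
                                                 registration_check=False))
        assert np.array_equal(res.fused.values, b.values)

    def test_swapping_inputs_only_flips_tie_pixels(self, rng):
        base = 0.2 + 0.01 * rng.standard_normal((32, 32))
        s1 = np.zeros((32, 32))
        s1[10:13] = 0.04
        s2 = np.zeros((32, 32))
        s2[:, 20:23] = 0.04
        a, b = img(base + s1), img(base + s2)
        p = PipelineParams(metal_threshold=None, registration_check=False)
        r1 = tmar_pipeline(a, b, p)
        r2 = tmar_pipeline(b, a, p)
        ties = r1.c_ori.values == r1.c_tilt.values
        assert np.array_equal(r1.fused.values[~ties], r2.fused.values[~ties])

    def test_metal_pixels_copied_from_ordinary(self, rng):
        base = 0.2 + 0.005 * rng.standard_normal((32, 32))
        a = base.copy()
        a[15:17, 15:17] = 5.0  # implant visible only in the ordinary scan
        res = tmar_pipeline(img(a), img(base), PipelineParams(
            registration_check=False))
        assert np.array_equal(res.fused.values[15:17, 15:17], a[15:17, 15:17])
        assert res.metal_mask[15:17, 15:17].all()

    def test_misregistered_inputs_rejected(self, rng):
        base = 0.2 * np.ones((48, 48))
        a = base.copy()
        a[10:20, 10:20] = 0.6  # "bone" block
        b = base.copy()
        b[28:38, 28:38] = 0.6  # same block, far away
        with pytest.raises(ValueError, match="misregistered"):
            tmar_pipeline(img(a), img(b))

    def test_atmar_second_pass_disabled_is_tmar(self, rng):
        v = 0.2 + 0.01 * rng.standard_normal((32, 32))
        a, b = img(v), img(v + 0.005)
        p = PipelineParams(metal_threshold=None, registration_check=False)
        r1 = tmar_pipeline(a, b, p)
        r2 = atmar_pipeline(a, b, p, second_pass=False)
        assert np.array_equal(r1.fused.values, r2.fused.values)

    def test_atmar_with_explicit_augment_runs_two_stages(self, rng):
        v = 0.2 + 0.01 * rng.standard_normal((32, 32))
        a, b = img(v), img(v + 0.01 * rng.standard_normal((32, 32)))
        aug = img(v.copy())
        p = PipelineParams(metal_threshold=None, registration_check=False)
        res = atmar_pipeline(a, b, p, augment=aug)
        assert res.stage1 is not None
        assert res.augment is aug
        member = np.isclose(res.fused.values, res.stage1.fused.values) \
            | np.isclose(res.fused.values, aug.values)
        assert member.all()
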