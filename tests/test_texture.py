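"""Texture feature families against brute-force oracles and known limits."""

import numpy as np
import pytest

from thyrotex import (ROIMask, TextureConfig, ar_features, extract_all,
                      feature_names, geometry_features, glcm, glcm_features,
                      gradient_features, histogram_features, quantize_roi,
                      rlm_features, wavelet_features)
from thyrotex.texture import GLCMatrix, RLM_DIRECTIONS

from .oracles import (geometry_brute, glcm_brute, gradient_brute,
                      haralick_brute, rlm_brute)


def full_roi(shape):
    return ROIMask(mask=np.ones(shape, bool))


class TestQuantize:
    @pytest.mark.parametrize("norm", ["minmax", "mu3sigma", "perc1_99"])
    def test_constant_roi_maps_to_level_one(self, norm):
        q = quantize_roi(np.full((4, 4), 3.0), full_roi((4, 4)), 6, norm)
        assert (q.levels[q.mask.mask] == 1).all()

    def test_binary_values_minmax_one_bit(self):
        raster = np.array([[0.0, 1.0], [1.0, 0.0]])
        q = quantize_roi(raster, full_roi((2, 2)), 1, "minmax")
        assert set(q.levels.ravel()) == {1, 2}
        assert q.G == 2

    def test_perc1_99_clips_tails(self, rng):
        vals = rng.uniform(0, 1, 100).reshape(10, 10)
        q = quantize_roi(vals, full_roi((10, 10)), 6, "perc1_99")
        srt = np.sort(vals.ravel())
        # at most 2 values fall outside [P1, P99] at each end
        lo, hi = np.percentile(vals, [1, 99])
        assert (srt < lo).sum() <= 2 and (srt > hi).sum() <= 2
        assert (q.levels[q.mask.mask] == 1).sum() >= (srt < lo).sum()
        assert (q.levels[q.mask.mask] == q.G).sum() >= (srt > hi).sum()

    def test_levels_within_range_and_monotone(self, rng):
        vals = rng.normal(size=(9, 9))
        q = quantize_roi(vals, full_roi((9, 9)), 4, "mu3sigma")
        inroi = q.levels[q.mask.mask]
        assert inroi.min() >= 1 and inroi.max() <= 16
        order = np.argsort(vals.ravel())
        assert (np.diff(q.levels.ravel()[order]) >= 0).all()

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            ROIMask(mask=np.zeros((3, 3), bool))


class TestGLCM:
    def test_two_pixel_pair(self):
        levels = np.array([[1, 2]])
        q = quantize_roi(np.array([[0.0, 1.0]]), full_roi((1, 2)), 1, "minmax")
        m = glcm(q, (1, 0))
        assert m.p[0, 1] == pytest.approx(0.5)
        assert m.p[1, 0] == pytest.approx(0.5)

    def test_constant_roi_point_mass(self):
        q = quantize_roi(np.full((3, 3), 2.0), full_roi((3, 3)), 2, "minmax")
        m = glcm(q, (0, 1))
        assert m.p[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("offset", [(1, 0), (0, 1), (2, -2), (3, 3), (5, 0)])
    def test_matches_exhaustive_pair_count(self, rng, offset):
        raster = rng.normal(size=(8, 8))
        mask = rng.random((8, 8)) < 0.7
        mask[0, 0] = True
        roi = ROIMask(mask=mask)
        q = quantize_roi(raster, roi, 3, "minmax")
        m = glcm(q, offset)
        ref = glcm_brute(q.levels, mask, offset, q.G)
        assert np.allclose(m.p, ref, atol=1e-12)

    def test_symmetric_and_normalized(self, rng):
        raster = rng.normal(size=(8, 8))
        q = quantize_roi(raster, full_roi((8, 8)), 4, "mu3sigma")
        m = glcm(q, (1, -1))
        assert np.allclose(m.p, m.p.T)
        assert m.p.sum() == pytest.approx(1.0)

    def test_degenerate_offset_flagged(self):
        q = quantize_roi(np.ones((1, 1)), full_roi((1, 1)), 2, "minmax")
        m = glcm(q, (5, 0))
        assert m.degenerate and m.p.sum() == 0


class TestGLCMFeatures:
    def test_point_mass_limits(self):
        p = np.zeros((4, 4))
        g = 2  # level index 3 (1-based)
        p[g, g] = 1.0
        f = glcm_features(GLCMatrix(p=p, offset=(1, 0)))
        assert f["SumAverg"] == pytest.approx(2 * (g + 1))
        assert f["Entropy"] == pytest.approx(0.0)
        assert f["Contrast"] == pytest.approx(0.0)

    def test_two_level_symmetric_pair(self):
        p = np.zeros((4, 4))
        p[0, 1] = p[1, 0] = 0.5
        f = glcm_features(GLCMatrix(p=p, offset=(1, 0)))
        assert f["DifEntrp"] == pytest.approx(0.0)
        assert f["SumAverg"] == pytest.approx(3.0)

    def test_matches_textbook_oracle_on_random_matrices(self, rng):
        for _ in range(10):
            raw = rng.random((4, 4))
            p = raw + raw.T
            p /= p.sum()
            f = glcm_features(GLCMatrix(p=p, offset=(1, 0)))
            ref = haralick_brute(p)
            for name, val in ref.items():
                assert f[name] == pytest.approx(val, abs=1e-12), name


class TestRLM:
    def test_single_run(self):
        q = quantize_roi(np.full((1, 5), 2.0), full_roi((1, 5)), 2, "minmax")
        f = rlm_features(q, "Horzl")
        assert f["LngREmph"] == pytest.approx(25.0)
        assert f["Fraction"] == pytest.approx(1 / 5)

    def test_alternating_row(self):
        raster = np.array([[0.0, 1.0, 0.0, 1.0]])
        q = quantize_roi(raster, full_roi((1, 4)), 1, "minmax")
        f = rlm_features(q, "Horzl")
        assert f["ShrtREmp"] == pytest.approx(1.0)
        assert f["LngREmph"] == pytest.approx(1.0)

    @pytest.mark.parametrize("direction", list(RLM_DIRECTIONS))
    def test_matches_run_scan_oracle(self, rng, direction):
        raster = rng.normal(size=(8, 8))
        mask = rng.random((8, 8)) < 0.7
        mask[3, 3] = True
        roi = ROIMask(mask=mask)
        q = quantize_roi(raster, roi, 2, "minmax")
        f = rlm_features(q, direction)
        rr, cc = np.nonzero(mask)
        sub = np.s_[rr.min():rr.max() + 1, cc.min():cc.max() + 1]
        ref = rlm_brute(q.levels[sub], mask[sub], RLM_DIRECTIONS[direction])
        for name, val in ref.items():
            assert f[name] == pytest.approx(val, abs=1e-12), name


class TestHistogram:
    def test_constant_roi_degenerate_moments(self):
        f = histogram_features(np.full((3, 3), 4.0), full_roi((3, 3)))
        assert f["Variance"] == 0.0
        assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0

    def test_median_linear_interpolation(self):
        raster = np.arange(1, 101, dtype=float).reshape(10, 10)
        f = histogram_features(raster, full_roi((10, 10)))
        assert f["Perc.50%"] == pytest.approx(50.5)
        assert f["Mean"] == pytest.approx(50.5)

    def test_symmetric_values_zero_skew(self):
        raster = np.array([[-2.0, -1.0, 0.0, 1.0, 2.0]])
        f = histogram_features(raster, full_roi((1, 5)))
        assert f["Skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_percentiles_from_sorted_order(self, rng):
        vals = rng.normal(size=(6, 6))
        f = histogram_features(vals, full_roi((6, 6)))
        for pc, name in [(1, "Perc.01%"), (10, "Perc.10%"), (90, "Perc.90%"),
                         (99, "Perc.99%")]:
            assert f[name] == pytest.approx(np.percentile(vals, pc))


class TestGradient:
    def test_constant_raster_zero(self):
        f = gradient_features(np.full((5, 5), 2.0), full_roi((5, 5)))
        assert f["GrMean"] == 0.0 and f["GrNonZeros"] == 0.0

    def test_linear_ramp_slope(self):
        raster = 0.7 * np.arange(6)[None, :] * np.ones((6, 1))
        f = gradient_features(raster, full_roi((6, 6)))
        assert f["GrMean"] == pytest.approx(0.7)
        assert f["GrVariance"] == pytest.approx(0.0, abs=1e-15)

    def test_matches_loop_oracle(self, rng):
        raster = rng.normal(size=(8, 8))
        mask = rng.random((8, 8)) < 0.85
        mask[2:6, 2:6] = True
        f = gradient_features(raster, ROIMask(mask=mask))
        ref = gradient_brute(raster, mask)
        assert f["GrMean"] == pytest.approx(ref.mean())
        assert f["GrVariance"] == pytest.approx(ref.var())
        assert f["GrNonZeros"] == pytest.approx(np.mean(ref > 0))

    def test_no_interior_flagged_nan(self):
        f = gradient_features(np.ones((1, 5)), full_roi((1, 5)))
        assert all(np.isnan(v) for v in f.values())


class TestAutoregressive:
    def test_white_noise_thetas_near_zero(self):
        g = np.random.default_rng(5)
        raster = g.normal(size=(100, 100))
        f = ar_features(raster, full_roi((100, 100)))
        for k in ("Teta1", "Teta2", "Teta3", "Teta4"):
            assert abs(f[k]) < 0.03
        assert f["Sigma"] == pytest.approx(1.0, abs=0.05)

    def test_row_copy_exact_regressor(self):
        g = np.random.default_rng(6)
        col = g.normal(size=(10, 1))
        raster = np.tile(col, (1, 10))  # x(i,j) = x(i,j-1) exactly
        f = ar_features(raster, full_roi((10, 10)))
        assert f["Teta1"] == pytest.approx(1.0, abs=1e-8)
        assert f["Sigma"] == pytest.approx(0.0, abs=1e-8)

    def test_parameter_recovery_from_known_generator(self):
        g = np.random.default_rng(7)
        theta = np.array([0.4, -0.15, 0.3, 0.1])
        n = 120
        x = np.zeros((n, n))
        x[0, :] = g.normal(size=n)
        for i in range(1, n):
            x[i, 0] = g.normal()
            x[i, -1] = g.normal()
            for j in range(1, n - 1):
                x[i, j] = (theta[0] * x[i, j - 1] + theta[1] * x[i - 1, j - 1]
                           + theta[2] * x[i - 1, j] + theta[3] * x[i - 1, j + 1]
                           + g.normal())
        f = ar_features(x, full_roi((n, n)))
        est = np.array([f["Teta1"], f["Teta2"], f["Teta3"], f["Teta4"]])
        assert np.allclose(est, theta, atol=0.05)

    def test_too_few_pixels_flagged(self):
        f = ar_features(np.ones((2, 2)), full_roi((2, 2)))
        assert all(np.isnan(v) for v in f.values())


class TestWavelet:
    def test_constant_raster_zero_detail(self):
        f = wavelet_features(np.full((16, 16), 3.0), full_roi((16, 16)))
        for name, val in f.items():
            if "LL" not in name:
                assert val == pytest.approx(0.0, abs=1e-20), name

    def test_single_hh_basis_function(self):
        raster = np.zeros((8, 8))
        raster[2:4, 4:6] = [[0.5, -0.5], [-0.5, 0.5]]
        f = wavelet_features(raster, full_roi((8, 8)))
        assert f["WavEnHH_s-1"] > 0
        for name in ("WavEnLH_s-1", "WavEnHL_s-1", "WavEnLH_s-2",
                     "WavEnHL_s-2", "WavEnHH_s-2", "WavEnHH_s-3"):
            assert f[name] == pytest.approx(0.0, abs=1e-20), name

    def test_scale1_energy_matches_block_filter_oracle(self, rng):
        raster = rng.normal(size=(8, 8))
        f = wavelet_features(raster, full_roi((8, 8)), scales=(1,))
        # direct 2x2 Haar block transform
        blocks = raster.reshape(4, 2, 4, 2).transpose(0, 2, 1, 3)
        a = blocks[..., 0, 0]
        b = blocks[..., 0, 1]
        c = blocks[..., 1, 0]
        d = blocks[..., 1, 1]
        ll = (a + b + c + d) / 2
        lh = (a - b + c - d) / 2   # horizontal detail
        hl = (a + b - c - d) / 2   # vertical detail
        hh = (a - b - c + d) / 2
        assert f["WavEnLL_s-1"] == pytest.approx(np.mean(ll**2))
        assert f["WavEnHH_s-1"] == pytest.approx(np.mean(hh**2))
        assert sorted([f["WavEnLH_s-1"], f["WavEnHL_s-1"]]) == \
            pytest.approx(sorted([np.mean(lh**2), np.mean(hl**2)]))

    def test_small_bounding_box_flagged(self):
        mask = np.zeros((16, 16), bool)
        mask[4:6, 4:10] = True  # bbox 2 x 6: scales 2 and 3 undefined
        f = wavelet_features(np.random.default_rng(0).normal(size=(16, 16)),
                             ROIMask(mask=mask))
        assert not np.isnan(f["WavEnHH_s-1"])
        assert np.isnan(f["WavEnHH_s-2"]) and np.isnan(f["WavEnHH_s-3"])


class TestGeometry:
    def test_single_pixel(self):
        mask = np.zeros((6, 6), bool)
        mask[4, 2] = True
        f = geometry_features(ROIMask(mask=mask))
        assert f["GeoX"] == 2 and f["GeoY"] == 4
        assert f["GeoM2xy"] == 0.0

    def test_centered_square_mixed_moment_zero(self):
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        f = geometry_features(ROIMask(mask=mask))
        assert f["GeoM2xy"] == pytest.approx(0.0)

    def test_matches_pixel_sum_oracle(self, rng):
        mask = rng.random((8, 8)) < 0.5
        mask[1, 1] = True
        f = geometry_features(ROIMask(mask=mask))
        ref = geometry_brute(mask)
        for name, val in ref.items():
            assert f[name] == pytest.approx(val, abs=1e-12), name


class TestExtractAll:
    def test_feature_count_matches_registry(self, rng):
        raster = rng.normal(size=(32, 32))
        mask = np.zeros((32, 32), bool)
        mask[4:28, 6:26] = True
        config = TextureConfig()
        feats = extract_all(raster, ROIMask(mask=mask), config)
        names = feature_names(config)
        assert list(feats) == names
        assert len(names) == 278
        assert not any(np.isnan(v) for v in feats.values())

    def test_deterministic(self, rng):
        raster = rng.normal(size=(16, 16))
        roi = full_roi((16, 16))
        a = extract_all(raster, roi)
        b = extract_all(raster, roi)
        assert list(a) == list(b)
        assert all(a[k] == b[k] for k in a)

    def test_constant_shift_invariance_minmax(self, rng):
        raster = rng.normal(size=(16, 16))
        roi = full_roi((16, 16))
        config = TextureConfig(normalization="minmax", include_histogram=False,
                               include_gradient=False, include_ar=False,
                               include_wavelet=False)
        a = extract_all(raster, roi, config)
        b = extract_all(raster + 5.0, roi, config)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-12), k

    def test_rotation_maps_glcm_offsets(self, rng):
        raster = rng.normal(size=(12, 12))
        mask = rng.random((12, 12)) < 0.7
        mask[5, 5] = True
        a = extract_all(raster, ROIMask(mask=mask),
                        TextureConfig(normalization="minmax"))
        # rotate 90 deg counter-clockwise: rows <-> cols
        r90 = np.rot90(raster)
        m90 = np.rot90(mask)
        b = extract_all(r90, ROIMask(mask=m90),
                        TextureConfig(normalization="minmax"))
        for d in range(1, 6):
            for feat in ("Contrast", "SumAverg", "Entropy"):
                assert a[f"S({d},0){feat}"] == \
                    pytest.approx(b[f"S(0,{d}){feat}"], abs=1e-12)

    def test_geometry_disabled_by_config(self, rng):
        raster = rng.normal(size=(8, 8))
        feats = extract_all(raster, full_roi((8, 8)),
                            TextureConfig(include_geometry=False))
        assert not any(k.startswith("Geo") for k in feats)


class TestFeatureRegistry:
    def test_registry_matches_names_and_documents_every_feature(self):
        from thyrotex import feature_registry
        for config in (TextureConfig(),
                       TextureConfig(include_geometry=False, bits=4)):
            reg = feature_registry(config)
            assert list(reg) == feature_names(config)
            assert all(formula.strip() for formula in reg.values())
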