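import numpy as np
import pytest

from cervixnet.features import (
    ContourletVector,
    assemble,
    block_mean,
    compute_features,
    feature_matrix_shape,
    glcm_features,
    lbp,
    ltp,
    nsct_decompose,
    quantize,
)

from _oracles import glcm_pair_counts


class TestLBP:
    def test_constant_patch_codes_255(self):
        # equality maps to bit 1 under the inverted comparison rule
        assert (lbp(np.full((5, 5), 90)) == 255).all()

    def test_enumerated_neighbourhood(self):
        # clockwise from top-left: [9,2,7,3,8,1,6,4] around center 5
        patch = np.array([[9, 2, 7], [4, 5, 3], [6, 1, 8]])
        # bits (neighbor<=center): 9->0,2->1,7->0,3->1,8->0,1->1,6->0,4->1
        assert lbp(patch)[1, 1] == 0b01010101 == 85

    def test_shift_invariance(self, rng):
        img = rng.integers(0, 200, (12, 12))
        np.testing.assert_array_equal(lbp(img), lbp(img + 50))

    def test_standard_rule_complements_strict_comparisons(self, rng):
        img = rng.random((10, 10)) * 255  # continuous: ties have measure zero
        assert ((lbp(img, rule="inverted") + lbp(img, rule="standard")) == 255).all()

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            lbp(np.zeros((4, 4)), rule="bogus")


class TestLTP:
    def test_constant_patch_all_zero(self):
        maps = ltp(np.full((6, 6), 120), t=5)
        assert (maps.upper == 0).all() and (maps.lower == 0).all()

    def test_zero_tolerance_upper_complements_lbp(self, rng):
        img = rng.integers(0, 256, (9, 9))
        maps = ltp(img, t=0)
        np.testing.assert_array_equal(maps.upper, 255 - lbp(img))

    def test_single_hot_neighbour(self):
        patch = np.full((3, 3), 100)
        patch[0, 1] = 120  # top neighbour -> second bit of the code
        maps = ltp(patch, t=5)
        assert maps.upper[1, 1] == 0b01000000
        assert maps.lower[1, 1] == 0

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            ltp(np.zeros((3, 3)), t=-1)


class TestGLCM:
    def test_constant_image_degenerate(self):
        s = glcm_features(np.full((8, 8), 7), levels=8)
        assert s.energy == pytest.approx(1.0)
        assert s.entropy == pytest.approx(0.0)
        assert s.homogeneity == pytest.approx(1.0)
        assert s.correlation == 0.0

    def test_2x2_toy_single_pair(self):
        s = glcm_features(np.array([[0, 1], [1, 0]]), levels=2)
        # only co-occurring 45-degree pair is (1,1): energy 1, entropy 0
        assert s.energy == pytest.approx(1.0)
        assert s.entropy == pytest.approx(0.0)

    def test_matches_bruteforce_pair_counts(self, rng):
        img = rng.integers(0, 256, (14, 11))
        levels = 8
        q = quantize(img, levels)
        ref = glcm_pair_counts(q, levels, (-1, 1))
        s = glcm_features(img, levels=levels)
        assert s.energy == pytest.approx((ref**2).sum())
        nz = ref[ref > 0]
        assert s.entropy == pytest.approx(float(-(nz * np.log2(nz)).sum()))

    def test_checkerboard_has_positive_entropy(self):
        board = np.indices((8, 8)).sum(axis=0) % 2 * 255
        assert glcm_features(board, levels=2).entropy > 0.0


class TestNSCT:
    def test_perfect_reconstruction(self, rng):
        img = rng.random((32, 48)) * 255
        cv = nsct_decompose(img)
        np.testing.assert_allclose(cv.reconstruct(), img, atol=1e-6)

    def test_constant_image_energy_in_lowpass(self):
        cv = nsct_decompose(np.full((16, 16), 80.0))
        for name, band in cv.bands.items():
            if name == "lowpass":
                np.testing.assert_allclose(band, 80.0, atol=1e-9)
            else:
                np.testing.assert_allclose(band, 0.0, atol=1e-9)

    def test_shift_equivariance(self, rng):
        img = rng.random((32, 32)) * 255
        cv = nsct_decompose(img)
        cv_shift = nsct_decompose(np.roll(img, (1, 0), axis=(0, 1)))
        for name in cv.bands:
            np.testing.assert_allclose(
                cv_shift.bands[name], np.roll(cv.bands[name], (1, 0), axis=(0, 1)), atol=1e-9
            )

    def test_band_count_and_order(self, rng):
        cv = nsct_decompose(rng.random((16, 16)), dirs=(4, 2))
        assert cv.band_names == ("s1_d0", "s1_d1", "s1_d2", "s1_d3", "s2_d0", "s2_d1", "lowpass")
        assert cv.flatten().shape == (7 * 16 * 16,)

    def test_three_stages_rejected(self):
        with pytest.raises(ValueError):
            nsct_decompose(np.zeros((16, 16)), stages=3)


class TestBlockMean:
    def test_exact_division(self):
        img = np.arange(16.0).reshape(4, 4)
        out = block_mean(img, (2, 2))
        np.testing.assert_allclose(out, [[2.5, 4.5], [10.5, 12.5]])

    def test_uneven_division_preserves_total_mean(self, rng):
        img = rng.random((13, 17))
        out = block_mean(img, (4, 4))
        assert out.shape == (4, 4)
        assert np.isfinite(out).all()


class TestAssemble:
    def test_fixed_shape_regardless_of_input_size(self, cfg):
        for size in ((64, 64), (96, 128)):
            img = np.random.default_rng(1).random(size) * 255
            fm = compute_features(img)
            assert fm.shape == feature_matrix_shape((16, 16), (4, 2)) == (161, 16)

    def test_values_bounded_and_finite(self, rng):
        fm = compute_features(rng.random((64, 64)) * 255)
        assert np.isfinite(fm.values).all()
        assert fm.values.min() >= 0.0 and fm.values.max() <= 1.0

    def test_zero_image_blocks(self):
        fm = compute_features(np.zeros((32, 32)))
        assert (fm.channel("lbp") == 1.0).all()  # constant image codes 255
        for name in ("s1_d0", "s2_d1"):
            np.testing.assert_allclose(fm.channel(name), 0.5, atol=1e-7)  # centered zeros
        glcm_row = fm.channel("glcm")[0]
        np.testing.assert_allclose(glcm_row[:4], 1.0)   # energy segment
        np.testing.assert_allclose(glcm_row[4:8], 0.5)  # degenerate correlation
        np.testing.assert_allclose(glcm_row[8:12], 0.0)  # entropy
        np.testing.assert_allclose(glcm_row[12:], 1.0)  # homogeneity

    def test_layout_roundtrip_recovers_lbp_block(self, rng):
        img = rng.random((64, 64)) * 255
        from cervixnet.features import lbp as lbp_fn

        fm = compute_features(img)
        recovered = fm.channel("lbp").astype(np.float64) * 255.0
        np.testing.assert_allclose(recovered, block_mean(lbp_fn(img), (16, 16)), rtol=1e-5)

    def test_assembly_from_parts_matches_layout(self, rng):
        img = rng.random((32, 32)) * 255
        fm = assemble(
            lbp(img), ltp(img), glcm_features(img), nsct_decompose(img), grid=(8, 8)
        )
        assert fm.shape == (10 * 8 + 1, 8)
        assert fm.layout["glcm"] == (80, 81)
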