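import numpy as np
import pytest

from cervixnet.dnrf import (
    DIRECTIONS,
    classify_pixel,
    decide,
    denoise,
    detect,
    extract_directions,
    heuristic_metric,
    trim_sort,
)

from _oracles import dnrf_reference


def impulse_image(base, positions, values):
    img = base.copy()
    for (r, c), v in zip(positions, values):
        img[r, c] = v
    return img


class TestExtractDirections:
    def test_constant_window(self):
        samples = extract_directions(np.full((11, 11), 7, dtype=np.uint8))
        assert tuple(s.direction for s in samples) == DIRECTIONS
        for s in samples:
            assert s.raw.shape == (11,)
            assert (s.raw == 7).all()

    def test_middle_row_is_horizontal(self):
        win = np.zeros((11, 11), dtype=np.uint8)
        win[5, :] = np.arange(11)
        h = extract_directions(win)[0]
        np.testing.assert_array_equal(h.raw, np.arange(11))

    def test_lines_cover_41_distinct_cells(self):
        win = np.arange(121).reshape(11, 11)
        cells = set()
        for s in extract_directions(win):
            cells.update(s.raw.tolist())
        assert len(cells) == 41  # 4*11 - 3 shared centers

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            extract_directions(np.zeros((10, 11)))


class TestTrimSort:
    def test_hand_enumerated_example(self):
        from cervixnet.dnrf import DirectionalSample

        raw = np.array([10, 12, 11, 14, 13, 50, 12, 11, 10, 13, 12])
        s = trim_sort(DirectionalSample("horizontal", raw))
        np.testing.assert_array_equal(s.trimmed, [10, 11, 11, 12, 12, 12, 13, 13])

    def test_constant_gives_zero_sigma(self):
        from cervixnet.dnrf import DirectionalSample

        s = trim_sort(DirectionalSample("vertical", np.full(11, 7)))
        assert (s.trimmed == 7).all() and s.trimmed.size == 8
        assert s.sigma == 0.0

    def test_center_removed_by_position_not_value(self):
        from cervixnet.dnrf import DirectionalSample

        # center value 12 occurs three times; the center slot goes by
        # position, then the extreme trim removes one more 12 as maximum,
        # leaving exactly one (value-based removal would leave none)
        raw = np.array([12, 1, 2, 3, 4, 12, 5, 6, 7, 8, 12])
        s = trim_sort(DirectionalSample("horizontal", raw))
        assert np.count_nonzero(s.trimmed == 12) == 1


class TestHeuristicMetric:
    @pytest.mark.parametrize(
        "center, trimmed, expected",
        [
            (7, np.full(8, 7), 0.0),
            (255, np.full(8, 10), 245.0),
            (12, np.array([10, 11, 11, 12, 12, 12, 13, 13]), 0.75),
        ],
    )
    def test_mean_absolute_deviation(self, center, trimmed, expected):
        assert heuristic_metric(center, trimmed) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            heuristic_metric(1, np.array([]))

    def test_mean_diff_mode(self):
        assert heuristic_metric(20, np.array([10.0, 14.0]), mode="mean_diff") == pytest.approx(8.0)


class TestClassifyPixel:
    def test_thresholding_is_strict(self):
        assert not classify_pixel(0.0, 20.0)
        assert classify_pixel(245.0, 20.0)
        assert not classify_pixel(20.0, 20.0)  # boundary: not noisy

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_pixel(1.0, 0.0)


class TestDenoise:
    def test_constant_image_untouched(self):
        img = np.full((16, 16), 42, dtype=np.uint8)
        out, mask = denoise(img)
        np.testing.assert_array_equal(out, img)
        assert mask.sum() == 0

    def test_single_impulse_detected_and_averaged(self):
        img = np.full((21, 21), 10, dtype=np.uint8)
        img[10, 10] = 255
        out, mask = denoise(img, threshold=20.0)
        assert mask[10, 10] == 1 and mask.sum() == 1
        assert out[10, 10] == 10  # mean of eight 10s
        np.testing.assert_array_equal(out[mask == 0], img[mask == 0])

    def test_clean_ramp_unaltered(self, ramp32):
        out, mask = denoise(ramp32, threshold=20.0)
        assert mask.sum() == 0
        np.testing.assert_array_equal(out, ramp32)

    def test_editing_gated_by_mask(self, rng):
        img = rng.integers(0, 256, (24, 24), dtype=np.uint8)
        out, mask = denoise(img)
        np.testing.assert_array_equal(out[mask == 0], img[mask == 0])

    def test_idempotent_on_clean_smooth_image(self, ramp32):
        once, _ = denoise(ramp32)
        twice, _ = denoise(once)
        np.testing.assert_array_equal(once, twice)

    def test_detection_monotone_in_impulse_amplitude(self, ramp32):
        positions = [(4, 5), (4, 20), (16, 10), (27, 27), (25, 3)]
        base = ramp32.astype(np.int64)
        prev = -1
        for amp in (30, 60, 120, 200):
            vals = [min(255, int(base[r, c]) + amp) for r, c in positions]
            img = impulse_image(base, positions, vals).astype(np.uint8)
            _, mask = denoise(img, threshold=20.0)
            count = int(mask.sum())
            assert count >= prev
            prev = count

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            denoise(np.zeros((8, 8), dtype=np.uint8))


class TestOracleEquivalence:
    def test_vectorized_matches_stepwise_reference(self, rng):
        """Per-pixel agreement with a literal reimplementation of the
        detect-sort-trim-decide-average procedure on a noisy 32x32 image."""
        y, x = np.mgrid[:32, :32].astype(np.float64)
        clean = np.rint(80 + 40 * np.sin(x / 6) + 30 * np.cos(y / 7)).astype(np.uint8)
        img = clean.copy()
        u = rng.random(img.shape)
        img[u < 0.025] = 0
        img[u > 0.975] = 255

        ref_out, ref_mask = dnrf_reference(img, threshold=20.0)
        out, mask = denoise(img, threshold=20.0)
        np.testing.assert_array_equal(mask.astype(bool), ref_mask)
        np.testing.assert_array_equal(out, ref_out)

        # filtering must strictly reduce error vs the clean image
        mae_before = np.abs(img.astype(float) - clean).mean()
        mae_after = np.abs(out.astype(float) - clean).mean()
        assert mae_after < mae_before

    def test_decide_matches_reference_choice(self, rng):
        win = rng.integers(0, 256, (11, 11), dtype=np.uint8)
        d = decide(win, threshold=20.0)
        hm_map, mask = detect(np.pad(win, 11, mode="reflect"), threshold=20.0)
        assert hm_map[16, 16] == pytest.approx(d.hm)
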