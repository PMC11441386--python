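import math

import numpy as np
import pytest
from scipy.spatial.distance import directed_hausdorff as scipy_dh
from skimage.filters import threshold_otsu as skimage_otsu

import mooneygen as mg


def oracle_otsu(img):
    """Exhaustive between-class-variance search straight from the pixels."""
    pix = np.asarray(img, np.float64).ravel()
    n = pix.size
    best_t, best_v = 0, -1.0
    for t in range(256):
        lo = pix[pix <= t]
        hi = pix[pix > t]
        if lo.size == 0 or hi.size == 0:
            v = 0.0
        else:
            w0, w1 = lo.size / n, hi.size / n
            v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_t, best_v = t, v
    return best_t


def oracle_max_edge(img, cfg=None):
    """Literal 256-iteration loop: binarize, detect edges, count, argmax."""
    counts = [mg.edge_pixel_count(mg.canny_edges(np.asarray(img) > t, cfg))
              for t in range(256)]
    return int(np.argmax(counts)), counts


def oracle_edge_similarity(img, cfg=None):
    """Literal 256-iteration loop scored by scipy's directed Hausdorff."""
    template = np.argwhere(mg.canny_edges(img, cfg))
    h, w = np.asarray(img).shape
    dists = []
    for t in range(256):
        pts = np.argwhere(mg.canny_edges(np.asarray(img) > t, cfg))
        if len(pts) == 0:
            dists.append(math.hypot(h, w))
        else:
            dists.append(scipy_dh(template, pts)[0])
    return int(np.argmin(dists)), dists


class TestApplyThreshold:
    def test_threshold_255_gives_all_black(self, bimodal):
        assert not mg.apply_threshold(bimodal, 255).pixels.any()

    def test_threshold_minus_one_gives_all_white(self, bimodal):
        assert mg.apply_threshold(bimodal, -1).pixels.all()

    def test_equality_is_black(self):
        img = np.array([[100, 150], [150, 200]], np.uint8)
        out = mg.apply_threshold(img, 150)
        np.testing.assert_array_equal(out.pixels, [[False, False], [False, True]])

    def test_uint8_encoding_is_0_255(self, bimodal):
        arr = mg.apply_threshold(bimodal, 120).to_uint8()
        assert set(np.unique(arr)) <= {0, 255}


class TestMeanThreshold:
    def test_constant_image(self):
        r = mg.mean_threshold(np.full((5, 5), 77, np.uint8))
        assert r.value == 77
        assert not mg.apply_threshold(np.full((5, 5), 77, np.uint8), r.value).pixels.any()

    def test_two_pixels(self):
        assert mg.mean_threshold(np.array([[0, 255]], np.uint8)).value == 127.5

    def test_full_ramp_mean(self):
        ramp = mg.make_fixture(mg.FixtureSpec("ramp", shape=(16, 16)))
        assert mg.mean_threshold(ramp).value == 127.5


class TestOtsuThreshold:
    def test_two_population_image(self):
        img = np.repeat(np.array([40, 200], np.uint8), 100).reshape(10, 20)
        r = mg.otsu_threshold(img)
        assert r.value == oracle_otsu(img)
        assert 40 <= r.value <= 199

    def test_binary_image_separates_populations(self):
        img = np.array([0] * 30 + [255] * 70, np.uint8).reshape(10, 10)
        r = mg.otsu_threshold(img)
        assert r.value == oracle_otsu(img)
        mooney = mg.apply_threshold(img, r.value)
        assert mooney.pixels.sum() == 70

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_on_random_images(self, seed):
        img = np.random.default_rng(seed).integers(0, 256, (16, 16)).astype(np.uint8)
        assert mg.otsu_threshold(img).value == oracle_otsu(img)

    def test_matches_skimage_cross_check(self, bimodal):
        assert mg.otsu_threshold(bimodal).value == skimage_otsu(bimodal)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="single intensity"):
            mg.otsu_threshold(np.full((8, 8), 42, np.uint8))

    def test_curve_attains_optimum(self, bimodal):
        r = mg.otsu_threshold(bimodal)
        assert r.objective_curve[int(r.value)] == r.objective_curve.max()


class TestMaxEdgeThreshold:
    def test_constant_image_tie_breaks_to_zero(self):
        r = mg.max_edge_threshold(np.full((16, 16), 99, np.uint8))
        assert r.value == 0
        assert np.all(r.objective_curve == 0)

    def test_matches_reference_loop_on_nested_rects(self, nested_rects):
        r = mg.max_edge_threshold(nested_rects)
        t_ref, counts = oracle_max_edge(nested_rects)
        assert r.value == t_ref
        np.testing.assert_array_equal(r.objective_curve, counts)

    def test_curve_at_255_is_zero(self, bimodal):
        assert mg.max_edge_threshold(bimodal).objective_curve[255] == 0


class TestEdgeSimilarityThreshold:
    def test_binary_input_reaches_distance_zero(self):
        img, _ = mg.make_fixture(mg.FixtureSpec("polarity_pair", shape=(32, 32)))
        r = mg.edge_similarity_threshold(img)
        assert r.objective_curve.min() == 0.0
        assert r.objective_curve[int(r.value)] == 0.0

    def test_matches_reference_loop_on_nested_rects(self, nested_rects):
        r = mg.edge_similarity_threshold(nested_rects)
        t_ref, dists = oracle_edge_similarity(nested_rects)
        assert r.value == t_ref
        np.testing.assert_allclose(r.objective_curve, dists, atol=1e-9)

    def test_curve_at_255_is_diagonal_sentinel(self, nested_rects):
        r = mg.edge_similarity_threshold(nested_rects)
        assert r.objective_curve[255] == pytest.approx(math.hypot(64, 64))

    def test_edgeless_template_rejected(self):
        with pytest.raises(ValueError, match="no Canny edges"):
            mg.edge_similarity_threshold(np.full((16, 16), 10, np.uint8))


class TestGenerateMooney:
    def test_constant_input_mean_gives_all_black(self):
        rgb = np.full((16, 16, 3), 120, np.uint8)
        mooney, result = mg.generate_mooney(rgb, 2.0, "mean")
        assert result.value == 120
        assert not mooney.pixels.any()

    def test_deterministic(self, bimodal):
        rgb = np.stack([bimodal] * 3, axis=-1)
        m1, r1 = mg.generate_mooney(rgb, 2.0, "otsu")
        m2, r2 = mg.generate_mooney(rgb, 2.0, "otsu")
        assert r1.value == r2.value
        np.testing.assert_array_equal(m1.pixels, m2.pixels)

    @pytest.mark.parametrize("technique", mg.TECHNIQUES)
    def test_composition_matches_manual_pipeline(self, technique, bimodal):
        rgb = np.stack([bimodal] * 3, axis=-1)
        mooney, result = mg.generate_mooney(rgb, 2.0, technique)
        gray8 = mg.preprocess(rgb, mg.SmoothingConfig(sigma=2.0))
        manual = mg.select_threshold(gray8, technique)
        assert result.value == manual.value
        np.testing.assert_array_equal(
            mooney.pixels, mg.apply_threshold(gray8, manual.value).pixels
        )

    def test_unknown_technique_rejected(self, bimodal):
        with pytest.raises(ValueError, match="unknown technique"):
            mg.generate_mooney(bimodal, 2.0, "adaptive")


class TestNestedness:
    def test_white_sets_are_nested_across_thresholds(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            img = rng.integers(0, 256, (12, 12)).astype(np.uint8)
            t1, t2 = sorted(rng.integers(0, 255, 2).tolist())
            if t1 == t2:
                t2 += 1
            hi = mg.apply_threshold(img, t2).pixels
            lo = mg.apply_threshold(img, t1).pixels
            assert np.all(lo[hi])  # white at t2 implies white at t1

    def test_selected_values_lie_in_image_range(self, bimodal):
        lo, hi = int(bimodal.min()), int(bimodal.max())
        for technique in mg.TECHNIQUES:
            value = mg.select_threshold(bimodal, technique).value
            assert lo <= value <= hi
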