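import numpy as np
import pytest
from skimage.feature import graycomatrix
from skimage.measure import moments_central, moments_hu, moments_normalized

from eegmap import (
    ConfigurationError,
    asm,
    compute_glcm,
    extract_traditional,
    glcm_entropy,
    glcm_features,
    haralick_features,
    hu_moments,
    lbp_code,
    lbp_features,
)
from eegmap.texture import HARALICK_NAMES, LBPConfig, lbp_code_map

from oracles import brute_central_moment, brute_glcm, brute_haralick, brute_lbp_code


class TestGLCM:
    def test_hand_enumerated_two_level_example(self):
        image = np.array([[0, 0], [1, 1]]) * 255
        p = compute_glcm(image, offsets=((0, 1),), levels=2, symmetric=True)
        np.testing.assert_allclose(p.p, [[0.5, 0.0], [0.0, 0.5]])
        assert asm(p) == pytest.approx(0.5)
        assert glcm_entropy(p) == pytest.approx(1.0)

    def test_constant_image_single_entry(self):
        p = compute_glcm(np.full((4, 4), 128, dtype=int), levels=256)
        assert p.p[128, 128] == pytest.approx(1.0)
        assert asm(p) == pytest.approx(1.0)
        assert glcm_entropy(p) == pytest.approx(0.0)

    @pytest.mark.parametrize("symmetric", [True, False])
    def test_normalization_sums_to_one(self, small_images, symmetric):
        for image in small_images[:5]:
            p = compute_glcm(image, levels=8, symmetric=symmetric)
            assert p.p.sum() == pytest.approx(1.0)
            if symmetric:
                np.testing.assert_allclose(p.p, p.p.T)

    def test_matches_brute_force_counting(self, small_images):
        offsets = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
        for image in small_images[:10]:
            p = compute_glcm(image, offsets=offsets, levels=8, symmetric=True)
            np.testing.assert_allclose(p.p, brute_glcm(image, offsets, 8, True),
                                       atol=1e-12)

    def test_matches_skimage_graycomatrix(self, small_images):
        """Independent library cross-check at distance 1, angle 0."""
        for image in small_images[:10]:
            ours = compute_glcm(image, offsets=((0, 1),), levels=256, symmetric=True)
            theirs = graycomatrix(image, distances=[1], angles=[0], levels=256,
                                  symmetric=True, normed=True)[:, :, 0, 0]
            np.testing.assert_allclose(ours.p, theirs, atol=1e-12)

    def test_offset_exceeding_extent_rejected(self):
        with pytest.raises(ConfigurationError, match="offset"):
            compute_glcm(np.zeros((2, 2), dtype=int), offsets=((0, 5),), levels=2)


class TestHaralick:
    def test_returns_14_named_features(self, heatmap):
        fv = haralick_features(compute_glcm(heatmap.pixels, levels=16))
        assert len(fv) == 14
        assert fv.names == list(HARALICK_NAMES)

    def test_constant_image_degenerate_values(self):
        fv = haralick_features(compute_glcm(np.full((6, 6), 42, dtype=int)))
        named = dict(zip(fv.names, fv.values))
        assert named["asm"] == pytest.approx(1.0)
        assert named["contrast"] == pytest.approx(0.0)
        assert named["inverse_difference_moment"] == pytest.approx(1.0)
        assert named["entropy"] == pytest.approx(0.0)
        assert named["correlation"] == 0.0  # zero-variance fallback

    def test_asm_entropy_extremes_coincide(self, small_images):
        for image in small_images[:5]:
            p = compute_glcm(image, levels=8)
            assert (asm(p) == pytest.approx(1.0)) == (glcm_entropy(p) == pytest.approx(0.0))

    def test_matches_brute_force_oracle_on_25_random_images(self, small_images):
        """Acceptance-level oracle equivalence at 1e-8 on 25 random 8x8 images."""
        for image in small_images:
            p = compute_glcm(image, levels=8, symmetric=True)
            expected = brute_haralick(p.p)
            np.testing.assert_allclose(haralick_features(p).values, expected,
                                       atol=1e-8)


class TestLBP:
    def test_all_neighbors_brighter_gives_full_code(self):
        image = np.full((3, 3), 200, dtype=int)
        image[1, 1] = 10
        assert lbp_code(image, (1, 1), P=8, R=1) == 255

    def test_all_neighbors_darker_gives_zero(self):
        image = np.zeros((3, 3), dtype=int)
        image[1, 1] = 200
        assert lbp_code(image, (1, 1), P=8, R=1) == 0

    def test_exact_tie_sets_the_bit(self):
        # neighbor 0 (due east) equals the center; its bit must be 1
        image = np.zeros((3, 3), dtype=int)
        image[1, 1] = 100
        image[1, 2] = 100
        assert lbp_code(image, (1, 1), P=8, R=1) & 1 == 1

    def test_center_too_close_to_border_rejected(self):
        with pytest.raises(ConfigurationError, match="border"):
            lbp_code(np.zeros((5, 5), dtype=int), (0, 2), P=8, R=1)

    @pytest.mark.parametrize("R", [1, 2, 3])
    def test_codes_match_exhaustive_enumeration(self, R):
        """Every valid pixel of random 9x9 patches against the per-pixel oracle."""
        rng = np.random.default_rng(99)
        for _ in range(10):
            image = rng.integers(0, 256, size=(9, 9))
            codes = lbp_code_map(image, P=8, R=R)
            for r in range(R, 9 - R):
                for c in range(R, 9 - R):
                    assert codes[r - R, c - R] == brute_lbp_code(image, r, c, 8, R)

    def test_default_feature_length_48(self, heatmap):
        fv = lbp_features(heatmap.pixels)
        assert len(fv) == 48
        assert fv.names[0] == "lbp_P8_R1_bin00"

    def test_histograms_sum_to_one_per_neighborhood(self, heatmap):
        fv = lbp_features(heatmap.pixels)
        for start in range(0, 48, 16):
            assert fv.values[start:start + 16].sum() == pytest.approx(1.0)

    def test_additive_gray_shift_invariance(self):
        rng = np.random.default_rng(5)
        image = rng.integers(0, 200, size=(32, 32))  # headroom: no saturation
        shifted = image + 55
        np.testing.assert_allclose(
            lbp_features(image).values, lbp_features(shifted).values
        )

    def test_image_smaller_than_neighborhood_rejected(self):
        with pytest.raises(ConfigurationError, match="too small"):
            lbp_features(np.zeros((4, 4), dtype=int), LBPConfig(neighborhoods=((8, 3),)))


class TestHuMoments:
    @staticmethod
    def blob(rng, size=24):
        return rng.integers(0, 256, size=(size, size))

    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        image = self.blob(rng, 12)
        canvas = np.zeros((40, 40), dtype=int)
        canvas[3:15, 5:17] = image
        moved = np.zeros((40, 40), dtype=int)
        moved[20:32, 18:30] = image
        np.testing.assert_allclose(
            hu_moments(canvas).values, hu_moments(moved).values, atol=1e-8
        )

    def test_rotation_invariance_90_degrees(self):
        rng = np.random.default_rng(7)
        image = self.blob(rng)
        np.testing.assert_allclose(
            hu_moments(image).values,
            hu_moments(np.rot90(image).copy()).values,
            atol=1e-8,
        )

    def test_scale_stability_under_2x_upscaling(self):
        rng = np.random.default_rng(8)
        image = self.blob(rng)
        upscaled = np.repeat(np.repeat(image, 2, axis=0), 2, axis=1)
        ours, scaled = hu_moments(image).values, hu_moments(upscaled).values
        np.testing.assert_allclose(scaled, ours, atol=1e-3)

    def test_printed_exponent_is_not_scale_invariant(self):
        rng = np.random.default_rng(9)
        image = self.blob(rng)
        upscaled = np.repeat(np.repeat(image, 2, axis=0), 2, axis=1)
        a = hu_moments(image, exponent="printed").values
        b = hu_moments(upscaled, exponent="printed").values
        assert abs(a[0] - b[0]) > 1e-3 * abs(a[0])

    def test_centered_square_symmetry(self):
        canvas = np.zeros((21, 21), dtype=int)
        canvas[8:13, 8:13] = 100
        values = hu_moments(canvas).values
        assert values[0] > 0
        np.testing.assert_allclose(values[1:], 0.0, atol=1e-12)

    def test_central_moments_match_brute_force(self):
        rng = np.random.default_rng(10)
        image = self.blob(rng, 10)
        fv = hu_moments(image)
        # phi1 = eta20 + eta02 recomputed from brute-force central moments
        mu00 = brute_central_moment(image, 0, 0)
        phi1 = (
            brute_central_moment(image, 2, 0) + brute_central_moment(image, 0, 2)
        ) / mu00**2
        assert fv.values[0] == pytest.approx(phi1, abs=1e-12)

    def test_matches_skimage_hu(self):
        """Independent library cross-check of all seven invariants."""
        rng = np.random.default_rng(11)
        image = self.blob(rng).astype(float)
        theirs = moments_hu(moments_normalized(moments_central(image)))
        ours = hu_moments(image).values
        np.testing.assert_allclose(ours, theirs, rtol=1e-8, atol=1e-12)

    def test_all_zero_image_rejected(self):
        with pytest.raises(ConfigurationError):
            hu_moments(np.zeros((5, 5), dtype=int))


class TestExtractTraditional:
    @pytest.mark.parametrize(
        "which,length", [("glcm", 14), ("lbp", 48), ("hu", 7), ("all", 69)]
    )
    def test_lengths(self, heatmap, which, length):
        assert len(extract_traditional(heatmap, which=which)) == length

    def test_deterministic(self, heatmap):
        a = extract_traditional(heatmap, which="all")
        b = extract_traditional(heatmap, which="all")
        np.testing.assert_array_equal(a.values, b.values)
        assert a.names == b.names

    def test_unknown_extractor_rejected(self, heatmap):
        with pytest.raises(ConfigurationError, match="unknown extractor"):
            extract_traditional(heatmap, which="wavelet")
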