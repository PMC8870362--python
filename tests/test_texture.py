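"""Texture measures, co-occurrence construction, and TAM maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tamgcs import (
    TextureConfig,
    asm_measure,
    contrast_measure,
    cooccurrence,
    energy_measure,
    entropy_measure,
    homogeneity_measure,
    quantize,
    tam,
    tam_volume,
    texture_map,
)

CB4 = np.indices((4, 4)).sum(axis=0) % 2  # binary checkerboard
CFG2 = TextureConfig(levels=2, window=3, offsets=((0, 1),), symmetric=True)


def brute_cooccurrence(window, levels, offsets, symmetric):
    """Independent pair-enumeration oracle: explicit python loops."""
    h, w = window.shape
    counts = np.zeros((levels, levels))
    for dr, dc in offsets:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    counts[window[r, c], window[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def brute_convolve(image, kernel):
    """Naive O(n^2 k^2) zero-padded 'same' convolution (kernel flipped)."""
    h, w = image.shape
    kh, kw = kernel.shape
    ch, cw = kh // 2, kw // 2
    out = np.zeros((h, w))
    for x in range(h):
        for y in range(w):
            acc = 0.0
            for u in range(kh):
                for v in range(kw):
                    xi, yi = x - (u - ch), y - (v - cw)
                    if 0 <= xi < h and 0 <= yi < w:
                        acc += kernel[u, v] * image[xi, yi]
            out[x, y] = acc
    return out


class TestQuantize:
    def test_constant_maps_to_zero(self):
        assert np.all(quantize(np.full((5, 5), 3.7), 8) == 0)

    def test_binary_split_boundary(self):
        vals = np.arange(256, dtype=float).reshape(16, 16)
        q = quantize(vals, 2)
        expected = (vals >= 128).astype(int)
        np.testing.assert_array_equal(q, expected)

    def test_extremes_to_extreme_bins(self):
        np.testing.assert_array_equal(
            quantize(np.array([[0.0, 255.0], [255.0, 0.0]]), 2), [[0, 1], [1, 0]]
        )

    def test_matches_per_pixel_binning(self, rng):
        img = rng.uniform(-3, 7, size=(9, 9))
        L = 5
        q = quantize(img, L)
        lo, hi = img.min(), img.max()
        expected = np.minimum((img - lo) / (hi - lo) * L, L - 1).astype(int)
        np.testing.assert_array_equal(q, expected)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            quantize(np.array([[np.nan, 1.0]]), 2)


class TestCooccurrence:
    def test_constant_window_concentrates(self):
        p = cooccurrence(np.zeros((5, 5), dtype=int), TextureConfig(levels=4, window=5))
        assert p[0, 0] == 1.0 and p.sum() == 1.0

    def test_checkerboard_horizontal(self):
        p = cooccurrence(CB4, CFG2)
        np.testing.assert_allclose(p, [[0.0, 0.5], [0.5, 0.0]], atol=1e-15)

    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_enumeration_oracle(self, rng, symmetric):
        cfg = TextureConfig(levels=3, window=5, symmetric=symmetric)
        for _ in range(100):
            win = rng.integers(0, 3, size=(5, 5))
            p = cooccurrence(win, cfg)
            oracle = brute_cooccurrence(win, 3, cfg.offsets, symmetric)
            np.testing.assert_allclose(p, oracle, atol=1e-12)
            assert abs(p.sum() - 1.0) < 1e-12
            if symmetric:
                np.testing.assert_allclose(p, p.T, atol=1e-15)

    def test_matches_skimage_glcm(self, rng):
        """Independent route: skimage's GLCM at offset (0, 1)."""
        from skimage.feature import graycomatrix

        win = rng.integers(0, 4, size=(7, 7)).astype(np.uint8)
        cfg = TextureConfig(levels=4, window=7, offsets=((0, 1),), symmetric=True)
        ours = cooccurrence(win, cfg)
        ref = graycomatrix(win, [1], [0], levels=4, symmetric=True, normed=True)[:, :, 0, 0]
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_window_smaller_than_offsets_rejected(self):
        cfg = TextureConfig(levels=2, window=3, offsets=((0, 5),))
        with pytest.raises(ValueError):
            cooccurrence(np.zeros((3, 3), dtype=int), cfg)


def p_from_counts(counts):
    counts = np.asarray(counts, dtype=float)
    return counts / counts.sum()


class TestMeasures:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (np.eye(1), 0.0),
            ([[0.0, 0.5], [0.5, 0.0]], np.log(2)),
            (np.full((3, 3), 1 / 9), np.log(9)),
        ],
    )
    def test_entropy(self, p, expected):
        assert entropy_measure(np.asarray(p)) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "p, expected",
        [
            (np.diag([0.3, 0.7]), 0.0),
            ([[0.0, 0.5], [0.5, 0.0]], 1.0),
            ([[0, 0, 1.0], [0, 0, 0], [0, 0, 0]], 4.0),
        ],
    )
    def test_contrast(self, p, expected):
        assert contrast_measure(np.asarray(p)) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "p, expected",
        [
            (np.diag([0.3, 0.7]), 1.0),
            ([[0.0, 0.5], [0.5, 0.0]], 0.5),
            ([[0, 0, 1.0], [0, 0, 0], [0, 0, 0]], 0.2),
        ],
    )
    def test_homogeneity(self, p, expected):
        assert homogeneity_measure(np.asarray(p)) == pytest.approx(expected, abs=1e-12)

    def test_energy_conventions(self):
        p = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert asm_measure(p) == pytest.approx(0.5)
        assert energy_measure(p) == pytest.approx(np.sqrt(0.5))
        literal = TextureConfig(energy_as_sqrt=False)
        assert energy_measure(p, literal) == pytest.approx(0.5)
        one = np.zeros((3, 3))
        one[1, 2] = 1.0
        assert energy_measure(one) == pytest.approx(1.0)
        uniform = np.full((4, 4), 1 / 16)
        assert asm_measure(uniform) == pytest.approx(1 / 16)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_measure_bounds_on_random_distributions(self, seed):
        """Entropy in [0, log L^2]; contrast in [0, (L-1)^2]; homogeneity,
        ASM in their normalized ranges — for any co-occurrence matrix."""
        r = np.random.default_rng(seed)
        L = int(r.integers(2, 7))
        counts = r.integers(0, 20, size=(L, L))
        counts[0, 0] += 1  # at least one pair
        p = p_from_counts(counts)
        assert 0.0 <= entropy_measure(p) <= np.log(L**2) + 1e-12
        assert 0.0 <= contrast_measure(p) <= (L - 1) ** 2 + 1e-12
        assert 0.0 < homogeneity_measure(p) <= 1.0 + 1e-12
        assert 1.0 / L**2 - 1e-12 <= asm_measure(p) <= 1.0


class TestTextureMap:
    def test_constant_image(self):
        img = np.full((10, 10), 5.0)
        cfg = TextureConfig(levels=8, window=3)
        assert np.all(texture_map(img, "entropy", cfg) == 0.0)
        assert np.all(texture_map(img, "homogeneity", cfg) == 1.0)

    def test_two_halves_entropy_localized_to_boundary(self):
        """Interior of homogeneous halves has zero entropy; only a band
        of width < W around the boundary is nonzero."""
        img = np.zeros((12, 12))
        img[:, 6:] = 255.0
        cfg = TextureConfig(levels=2, window=3)
        t = texture_map(img, "entropy", cfg)
        assert np.all(t[:, :5] == 0.0)
        assert np.all(t[:, 8:] == 0.0)
        assert t[:, 5:8].max() > 0.0

    def test_consistent_with_windowed_cooccurrence(self, rng):
        """The vectorized map equals measure(cooccurrence(window)) per pixel."""
        img = rng.uniform(0, 255, size=(8, 8))
        cfg = TextureConfig(levels=4, window=3)
        q = quantize(img, 4)
        padded = np.pad(q, 1, mode="reflect")
        for measure, fn in [("entropy", entropy_measure), ("contrast", contrast_measure)]:
            t = texture_map(img, measure, cfg)
            for r in range(8):
                for c in range(8):
                    win = padded[r : r + 3, c : c + 3]
                    assert t[r, c] == pytest.approx(fn(cooccurrence(win, cfg)), abs=1e-12)

    def test_shift_invariance_interior(self, rng):
        img = rng.uniform(0, 255, size=(14, 14))
        cfg = TextureConfig(levels=4, window=3)
        t = texture_map(img, "contrast", cfg)
        shifted = np.roll(img, 2, axis=1)
        t2 = texture_map(shifted, "contrast", cfg)
        np.testing.assert_allclose(t2[3:-3, 5:-3], t[3:-3, 3:-5], atol=1e-12)

    def test_window_exceeding_image_rejected(self):
        with pytest.raises(ValueError):
            texture_map(np.zeros((5, 5)), "entropy", TextureConfig(window=7))


class TestTam:
    def test_identity_kernel_constant_homogeneity(self):
        res = tam(np.full((8, 8), 3.0), np.ones((1, 1)), "homogeneity")
        np.testing.assert_allclose(res.tam, 3.0)
        np.testing.assert_allclose(res.texture, 1.0)

    def test_kernel_scaling_scales_tam_only(self, rng):
        img = rng.uniform(0, 255, size=(8, 8))
        k = rng.normal(size=(3, 3))
        a, b = tam(img, k, "entropy"), tam(img, 2.5 * k, "entropy")
        np.testing.assert_allclose(b.tam, 2.5 * a.tam, rtol=1e-12)
        np.testing.assert_array_equal(a.texture, b.texture)

    def test_kernel_linearity(self, rng):
        img = rng.uniform(0, 255, size=(8, 8))
        k1, k2 = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
        combo = tam(img, 2.0 * k1 + 3.0 * k2, "contrast").tam
        parts = 2.0 * tam(img, k1, "contrast").tam + 3.0 * tam(img, k2, "contrast").tam
        np.testing.assert_allclose(combo, parts, atol=1e-9)

    def test_factorization_against_convolution_oracle(self, rng):
        img = rng.uniform(0, 255, size=(10, 10))
        k = rng.normal(size=(3, 3))
        cfg = TextureConfig(levels=4, window=3)
        res = tam(img, k, "entropy", cfg)
        expected = texture_map(img, "entropy", cfg) * brute_convolve(img, k)
        np.testing.assert_allclose(res.tam, expected, atol=1e-10)

    def test_normalize_mn_rescales_product_only(self, rng):
        img = rng.uniform(0, 255, size=(8, 8))
        k = np.ones((3, 3))
        cfg_off = TextureConfig(levels=4, window=3)
        cfg_on = TextureConfig(levels=4, window=3, normalize_mn=True)
        off, on = tam(img, k, "entropy", cfg_off), tam(img, k, "entropy", cfg_on)
        np.testing.assert_allclose(on.tam, off.tam / 9.0, rtol=1e-12)
        np.testing.assert_array_equal(on.texture, off.texture)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            tam(np.zeros((8, 8)), np.ones((2, 2)), "entropy")


class TestTamVolume:
    def test_single_slice_matches_2d(self, rng):
        img = rng.uniform(0, 255, size=(10, 10))
        k = np.ones((3, 3))
        cfg = TextureConfig(levels=4, window=3)
        vol = tam_volume(img[:, :, None], k, "entropy", cfg)
        np.testing.assert_array_equal(vol[:, :, 0], tam(img, k, "entropy", cfg).tam)

    def test_identical_slices_identical_outputs(self, rng):
        img = rng.uniform(0, 255, size=(10, 10))
        stack = np.repeat(img[:, :, None], 3, axis=2)
        out = tam_volume(stack, np.ones((3, 3)), "contrast", TextureConfig(levels=4, window=3))
        assert out.shape == (10, 10, 3)
        np.testing.assert_array_equal(out[:, :, 0], out[:, :, 1])
        np.testing.assert_array_equal(out[:, :, 0], out[:, :, 2])

    def test_empty_volume_rejected(self):
        with pytest.raises(ValueError):
            tam_volume(np.zeros((10, 10, 0)), np.ones((1, 1)), "entropy")
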