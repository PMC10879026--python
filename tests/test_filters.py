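"""Bilateral filter: weight formulas, brute-force oracle equivalence,
invariances, the Gaussian-blur limit, and the radial gradient index."""

import numpy as np
import pytest

from rbcdetect import (
    FilterParams,
    BilateralFilter,
    bilateral_filter,
    bilateral_weights,
    iterate_filter,
    radial_gradient_index,
)


def naive_bilateral(image, params):
    """Direct quadruple-loop evaluation of the weighted-average filter."""
    m, n = image.shape
    r = params.effective_radius
    out = np.zeros_like(image)
    for i in range(m):
        for j in range(n):
            acc = 0.0
            norm = 0.0
            for p in range(max(0, i - r), min(m, i + r + 1)):
                for q in range(max(0, j - r), min(n, j + r + 1)):
                    wd = np.exp(-((i - p) ** 2 + (j - q) ** 2) / (2 * params.sigma_d**2))
                    wr = np.exp(-((image[i, j] - image[p, q]) ** 2) / (2 * params.sigma_r**2))
                    acc += wd * wr * image[p, q]
                    norm += wd * wr
            out[i, j] = acc / norm
    return out


def truncated_gaussian_blur(image, sigma_d, radius):
    """Window-truncated, border-renormalized Gaussian blur oracle."""
    m, n = image.shape
    acc = np.zeros_like(image)
    norm = np.zeros_like(image)
    for dp in range(-radius, radius + 1):
        for dq in range(-radius, radius + 1):
            w = np.exp(-(dp * dp + dq * dq) / (2 * sigma_d**2))
            y0, y1 = max(0, -dp), min(m, m - dp)
            x0, x1 = max(0, -dq), min(n, n - dq)
            acc[y0:y1, x0:x1] += w * image[y0 + dp : y1 + dp, x0 + dq : x1 + dq]
            norm[y0:y1, x0:x1] += w
    return acc / norm


class TestWeights:
    def test_center_weight_is_one(self):
        img = np.random.default_rng(0).random((6, 6))
        assert bilateral_weights(img, 2, 3, 2, 3, FilterParams()) == (1.0, 1.0, 1.0)

    def test_adjacent_equal_intensity(self):
        img = np.full((4, 4), 0.5)
        wd, wr, w = bilateral_weights(img, 1, 1, 1, 2, FilterParams(sigma_d=1.0))
        assert wr == 1.0
        assert w == wd == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_range_weight_vanishes_for_small_sigma_r(self):
        img = np.zeros((3, 3))
        img[0, 1] = 1.0
        _, wr, _ = bilateral_weights(img, 0, 0, 0, 1, FilterParams(sigma_r=1e-4))
        assert wr < 1e-12

    def test_out_of_bounds_raises(self):
        with pytest.raises(IndexError):
            bilateral_weights(np.zeros((3, 3)), 0, 0, 5, 5, FilterParams())

    def test_weight_normalization_sums_to_one(self):
        # sum of w / W over the neighborhood is 1 at every pixel
        img = np.random.default_rng(1).random((7, 7))
        params = FilterParams(sigma_d=1.2, sigma_r=0.15, window_radius=2)
        r = params.effective_radius
        for i in range(7):
            for j in range(7):
                ws = [
                    bilateral_weights(img, i, j, p, q, params)[2]
                    for p in range(max(0, i - r), min(7, i + r + 1))
                    for q in range(max(0, j - r), min(7, j + r + 1))
                ]
                assert abs(sum(w / sum(ws) for w in ws) - 1.0) <= 1e-12


class TestBilateralFilter:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((8, 8))
        params = FilterParams(sigma_d=1.5, sigma_r=0.2, window_radius=2)
        assert np.max(np.abs(bilateral_filter(img, params) - naive_bilateral(img, params))) < 1e-10

    def test_constant_fixed_point(self):
        img = np.full((10, 10), 0.42)
        assert np.allclose(bilateral_filter(img, FilterParams()), img)

    def test_zero_radius_identity(self):
        img = np.random.default_rng(2).random((6, 6))
        assert np.array_equal(bilateral_filter(img, FilterParams(window_radius=0)), img)

    def test_output_within_input_range(self):
        img = np.random.default_rng(3).random((20, 20))
        out = bilateral_filter(img, FilterParams(sigma_d=2.0, sigma_r=0.3))
        assert out.min() >= img.min() - 1e-12 and out.max() <= img.max() + 1e-12

    def test_large_sigma_r_is_gaussian_blur(self):
        img = np.random.default_rng(4).random((16, 16))
        params = FilterParams(sigma_d=1.5, sigma_r=1e6, window_radius=4)
        blur = truncated_gaussian_blur(img, 1.5, 4)
        assert np.max(np.abs(bilateral_filter(img, params) - blur)) <= 1e-6

    def test_nonfinite_raises(self):
        bad = np.ones((4, 4))
        bad[0, 0] = np.inf
        with pytest.raises(ValueError):
            bilateral_filter(bad, FilterParams())


class TestIterateFilter:
    def test_constant_converges_immediately(self):
        img = np.full((8, 8), 0.5)
        out, n_used = iterate_filter(img, FilterParams(n_iterations=10))
        assert np.allclose(out, img) and n_used == 1

    def test_one_iteration_equals_single_pass(self):
        img = np.random.default_rng(5).random((10, 10))
        params = FilterParams(n_iterations=1, convergence_tol=0.0)
        out, n_used = iterate_filter(img, params)
        assert np.array_equal(out, bilateral_filter(img, params)) and n_used == 1

    def test_iterations_reduce_total_variation(self):
        rng = np.random.default_rng(6)
        img = np.full((32, 32), 0.5)
        salt = rng.random((32, 32)) < 0.05
        img[salt] = 1.0
        def tv(x):
            return np.abs(np.diff(x, axis=0)).sum() + np.abs(np.diff(x, axis=1)).sum()
        p1 = FilterParams(sigma_d=1.5, sigma_r=0.5, n_iterations=1, convergence_tol=0.0)
        p5 = FilterParams(sigma_d=1.5, sigma_r=0.5, n_iterations=5, convergence_tol=0.0)
        assert tv(iterate_filter(img, p5)[0]) <= tv(iterate_filter(img, p1)[0])

    def test_estimator_interface(self):
        img = np.random.default_rng(7).random((12, 12))
        est = BilateralFilter(sigma_d=1.0, sigma_r=0.2, n_iterations=2, convergence_tol=0.0)
        out = est.fit_transform(img)
        assert out.shape == img.shape and est.n_iterations_run_ == 2
        params = est.get_params()
        assert params["sigma_d"] == 1.0
        direct, _ = iterate_filter(img, FilterParams(sigma_d=1.0, sigma_r=0.2, n_iterations=2, convergence_tol=0.0))
        assert np.array_equal(out, direct)


class TestRadialGradientIndex:
    def test_constant_image_scores_zero(self):
        assert radial_gradient_index(np.full((32, 32), 0.5), (16, 16), 8) == 0.0

    def test_dark_blob_scores_high(self):
        yy, xx = np.mgrid[0:64, 0:64]
        blob = 1.0 - np.exp(-((xx - 32.0) ** 2 + (yy - 32.0) ** 2) / (2 * 8.0**2))
        assert radial_gradient_index(blob, (32, 32), 12) >= 0.95

    def test_off_center_evaluation_near_zero(self):
        yy, xx = np.mgrid[0:96, 0:96]
        blob = 1.0 - np.exp(-((xx - 24.0) ** 2 + (yy - 24.0) ** 2) / (2 * 6.0**2))
        # evaluated 3 radii away from the blob center
        assert abs(radial_gradient_index(blob, (24 + 3 * 18, 24), 6)) <= 0.3

    def test_disc_must_intersect_image(self):
        with pytest.raises(ValueError):
            radial_gradient_index(np.zeros((16, 16)), (100, 100), 3)
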