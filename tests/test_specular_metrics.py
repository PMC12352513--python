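"""Oracle and property tests for the highlight statistics."""

import warnings

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from glossjnd.specular_metrics import (MetricConfig, bandpass_decompose,
                                       coverage, histogram_skewness,
                                       metric_vector_for_pair,
                                       metrics_for_image, rms_contrast,
                                       sharpness_local_tv,
                                       sharpness_spectrum_slope,
                                       specular_component,
                                       threshold_highlights)
from glossjnd.synthetic_data import make_toy_images

CFG64 = MetricConfig(band_centers=(1, 2, 4, 8, 16, 24))


class TestSpecularComponent:
    def test_hand_oracle_2x2(self):
        full = np.array([[5.0, 2.0], [1.0, 1.0]])
        diffuse = np.array([[1.0, 1.0], [1.0, 2.0]])
        np.testing.assert_array_equal(specular_component(full, diffuse),
                                      [[4.0, 1.0], [0.0, 0.0]])

    def test_identity_and_annihilation(self):
        img = np.arange(9.0).reshape(3, 3)
        assert np.all(specular_component(img, img) == 0)
        np.testing.assert_array_equal(specular_component(img, np.zeros((3, 3))), img)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            specular_component(np.zeros((2, 2)), np.zeros((3, 3)))


class TestThreshold:
    def test_k0_keeps_positive_pixels(self):
        img = np.array([[0.0, 1.0], [2.0, 4.0]])
        out, hmask = threshold_highlights(img, 0, np.ones((2, 2), bool))
        assert hmask.sum() == 3 and out[0, 0] == 0

    def test_k40_hand_threshold(self):
        """Threshold = 0.4 * 4 = 1.6, so only {2, 4} survive."""
        img = np.array([[0.0, 1.0], [2.0, 4.0]])
        out, hmask = threshold_highlights(img, 40, np.ones((2, 2), bool))
        assert sorted(out[hmask]) == [2.0, 4.0]

    def test_uniform_image_all_retained(self):
        img = np.full((4, 4), 3.0)
        _, hmask = threshold_highlights(img, 39.9, np.ones((4, 4), bool))
        assert hmask.all()

    def test_all_zero_specular_no_error(self):
        _, hmask = threshold_highlights(np.zeros((4, 4)), 10, np.ones((4, 4), bool))
        assert not hmask.any()

    def test_coverage_non_increasing_in_k(self, rng):
        img = rng.uniform(0, 5, (32, 32))
        mask = np.ones((32, 32), bool)
        covs = [coverage(threshold_highlights(img, k, mask)[1], mask)
                for k in (0, 1, 3, 5, 10, 20, 30, 40)]
        assert np.all(np.diff(covs) <= 0)


class TestBandpass:
    def test_constant_image_all_bands_zero(self):
        bands = bandpass_decompose(np.full((64, 64), 7.0), CFG64)
        for b in bands:
            assert np.max(np.abs(b)) < 1e-8

    def test_sinusoid_lands_in_matching_band(self):
        """Grating at the 3rd band centre has maximal RMS in band 3."""
        f3 = CFG64.band_centers[2]
        img, _ = make_toy_images("sinusoid", size=64, frequency=f3)
        rms = [np.sqrt((b**2).mean()) for b in bandpass_decompose(img, CFG64)]
        assert int(np.argmax(rms)) == 2

    def test_linearity(self, rng):
        img = rng.uniform(0, 1, (64, 64))
        b1 = bandpass_decompose(img, CFG64)
        b3 = bandpass_decompose(3.0 * img, CFG64)
        for x, y in zip(b1, b3):
            np.testing.assert_allclose(3.0 * x, y, atol=1e-10)

    def test_above_nyquist_errors(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_decompose(np.zeros((32, 32)),
                               MetricConfig(band_centers=(4.0, 20.0)))


class TestScalarStats:
    def test_rms_contrast_oracles(self):
        mask2 = np.ones((1, 2), bool)
        assert rms_contrast(np.array([[5.0, 5.0]]), mask2) == 0
        assert rms_contrast(np.array([[0.0, 2.0]]), mask2) == 1.0

    def test_rms_contrast_homogeneity(self, rng):
        img = rng.uniform(0, 4, (16, 16))
        mask = rng.random((16, 16)) > 0.3
        np.testing.assert_allclose(rms_contrast(-2.5 * img, mask),
                                   2.5 * rms_contrast(img, mask))

    def test_coverage_counting(self):
        obj = np.zeros((4, 4), bool)
        obj[:3, :] = True  # 12 object pixels
        high = np.zeros((4, 4), bool)
        high[0, :3] = True  # 3 highlighted
        assert coverage(high, obj) == pytest.approx(0.25)
        assert coverage(np.zeros((4, 4), bool), obj) == 0.0
        assert coverage(obj, obj) == 1.0

    def test_skewness_oracles(self):
        mask = np.ones((2, 2), bool)
        assert histogram_skewness(np.array([[0.0, 1.0], [0.0, 1.0]]), mask) == pytest.approx(0.0)
        val = histogram_skewness(np.array([[0.0, 0.0], [0.0, 1.0]]), mask)
        assert val == pytest.approx(2 / np.sqrt(3), abs=1e-6)  # +1.1547
        shifted = histogram_skewness(np.array([[0.0, 0.0], [0.0, 1.0]]) + 5.0, mask)
        assert shifted == pytest.approx(val, abs=1e-12)

    def test_skewness_degenerate_is_nan(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert np.isnan(histogram_skewness(np.full((3, 3), 2.0),
                                               np.ones((3, 3), bool)))


class TestSharpness:
    def test_constant_image_tv_zero(self):
        img, mask = make_toy_images("uniform", size=64)
        assert sharpness_local_tv(img, mask) == 0.0

    def test_blur_decreases_both_measures(self):
        """Gaussian blur strips high frequencies: both sharpness measures drop."""
        for seed in range(5):
            img, mask = make_toy_images("noise", size=64, seed=seed)
            blurred = gaussian_filter(img, 2.0)
            assert sharpness_local_tv(blurred, mask) < sharpness_local_tv(img, mask)
            assert (sharpness_spectrum_slope(blurred, mask)
                    < sharpness_spectrum_slope(img, mask))

    def test_step_sharper_than_ramp(self):
        """Ideal step vs. equal-range ramp: step has larger local-max TV."""
        step, mask = make_toy_images("step_edge", size=64, amplitude=10.0)
        ramp, _ = make_toy_images("ramp", size=64, amplitude=10.0)
        assert sharpness_local_tv(step, mask) > sharpness_local_tv(ramp, mask)

    def test_all_constant_slope_is_nan_sentinel(self):
        img, mask = make_toy_images("uniform", size=64)
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(sharpness_spectrum_slope(img, mask))


class TestPairPredictors:
    def _pair_inputs(self, rng):
        full_ref = rng.uniform(1, 5, (64, 64))
        diff_ref = 0.5 * full_ref
        full_test = full_ref + rng.uniform(0, 1, (64, 64))
        mask = np.zeros((64, 64), bool)
        mask[8:56, 8:56] = True
        return full_ref, diff_ref, full_test, mask

    def test_identical_pair_all_zero(self, rng):
        fr, dr, _, mask = self._pair_inputs(rng)
        mv = metric_vector_for_pair(fr, dr, fr, dr, mask, 10, CFG64)
        assert mv.combined_contrast == 0 and mv.coverage == 0
        assert np.all(mv.band_contrast == 0) and mv.skewness == 0

    def test_symmetry_under_swap(self, rng):
        fr, dr, ft, mask = self._pair_inputs(rng)
        a = metric_vector_for_pair(fr, dr, ft, dr, mask, 10, CFG64)
        b = metric_vector_for_pair(ft, dr, fr, dr, mask, 10, CFG64)
        assert a.combined_contrast == pytest.approx(b.combined_contrast)
        assert a.coverage == pytest.approx(b.coverage)
        assert a.sharpness_tv == pytest.approx(b.sharpness_tv)

    def test_background_invariance(self, rng):
        """Randomizing pixels outside the object mask changes no metric."""
        fr, dr, ft, mask = self._pair_inputs(rng)
        base = metrics_for_image(fr, dr, mask, 5, CFG64)
        noisy_fr = fr.copy()
        noisy_fr[~mask] = rng.uniform(0, 100, (~mask).sum())
        pert = metrics_for_image(noisy_fr, dr, mask, 5, CFG64)
        for key in ("coverage", "combined_contrast", "skewness", "sharpness_tv"):
            assert base[key] == pytest.approx(pert[key]), key

    def test_finite_for_all_k_including_zero_specular(self):
        """Every statistic stays finite (or a documented NaN sentinel)."""
        img, mask = make_toy_images("planted_highlight", size=64)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for k in (0, 1, 3, 5, 10, 20, 30, 40):
                out = metrics_for_image(img, np.zeros_like(img), mask, k, CFG64)
                assert np.isfinite(out["combined_contrast"])
                assert np.isfinite(out["coverage"])
                zero = metrics_for_image(np.zeros_like(img), np.zeros_like(img),
                                         mask, k, CFG64)
                assert zero["coverage"] == 0.0
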