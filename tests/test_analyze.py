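"""SO2 maps, ROI statistics, FWHM diametry, regression, group tests."""
import numpy as np
import pytest

from msot import (ProfileLine, compare_groups, contrast_resolution,
                  diameter_regression, fwhm_diameter, roi_mean_spectrum,
                  so2_map)
from msot.analyze import sample_profile
from msot.phantom import ImageGrid
from msot.reconstruct import MultispectralImage
from msot.spectra import WavelengthGrid


class TestSo2Map:
    def test_pure_and_mixed_ratios(self):
        assert so2_map(np.array([[1.0]]), np.array([[0.0]]))[0, 0] == 1.0
        assert so2_map(np.array([[2.0]]), np.array([[2.0]]))[0, 0] == 0.5

    def test_low_total_pixels_masked(self):
        s = so2_map(np.array([[1e-9, 1.0]]), np.array([[1e-9, 1.0]]),
                    min_total=1e-3)
        assert s.mask[0, 0] and not s.mask[0, 1]

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            so2_map(np.array([[-1.0]]), np.array([[1.0]]))


class TestRoiMeanSpectrum:
    def _img(self, data):
        wl = WavelengthGrid(tuple(700 + 50 * i for i in range(data.shape[0])))
        return MultispectralImage(data=data, grid=wl,
                                  image_grid=ImageGrid(data.shape[1:], 0.1))

    def test_uniform_image_gives_constant_spectrum(self):
        img = self._img(np.full((3, 4, 4), 2.5))
        np.testing.assert_allclose(
            roi_mean_spectrum(img, np.ones((4, 4), bool)), 2.5)

    def test_union_linearity_for_equal_size_masks(self):
        rng = np.random.default_rng(0)
        img = self._img(rng.random((3, 4, 4)))
        m1 = np.zeros((4, 4), bool); m1[0, :2] = True
        m2 = np.zeros((4, 4), bool); m2[3, 2:] = True
        lhs = roi_mean_spectrum(img, m1 | m2)
        rhs = 0.5 * (roi_mean_spectrum(img, m1) + roi_mean_spectrum(img, m2))
        np.testing.assert_allclose(lhs, rhs)

    def test_empty_mask_rejected(self):
        img = self._img(np.ones((2, 3, 3)))
        with pytest.raises(ValueError):
            roi_mean_spectrum(img, np.zeros((3, 3), bool))


class TestContrastResolution:
    def test_closed_forms(self):
        img = np.zeros((4, 4))
        roi = np.zeros((4, 4), bool); roi[:2] = True
        bg = ~roi
        img[roi], img[bg] = 1.0, 1.0
        assert contrast_resolution(img, roi, bg) == pytest.approx(0.0)
        img[bg] = 0.0
        assert contrast_resolution(img, roi, bg) == pytest.approx(1.0)
        img[roi], img[bg] = 3.0, 1.0
        assert contrast_resolution(img, roi, bg) == pytest.approx(0.5)

    def test_overlapping_or_empty_masks_rejected(self):
        img = np.ones((3, 3))
        full = np.ones((3, 3), bool)
        with pytest.raises(ValueError):
            contrast_resolution(img, full, full)
        with pytest.raises(ValueError):
            contrast_resolution(img, np.zeros((3, 3), bool), full)


class TestFwhm:
    def _grid(self, n=81, pitch=0.02):
        return ImageGrid((3, n), pitch, origin_mm=(0.0, 0.0))

    def test_top_hat_width_recovered(self):
        grid = self._grid()
        img = np.zeros(grid.shape)
        x = grid.x_mm
        img[:, (x >= 0.65) & (x <= 0.95)] = 1.0      # 0.30 mm top-hat
        line = ProfileLine((0.0, 0.02), (1.6, 0.02), 0.01)
        m = fwhm_diameter(img, grid, line)
        assert m.fwhm_mm == pytest.approx(0.30, abs=0.03)

    def test_gaussian_fwhm_closed_form(self):
        grid = ImageGrid((3, 401), 0.01, origin_mm=(0.0, 0.0))
        x = grid.x_mm
        img = np.tile(np.exp(-0.5 * ((x - 2.0) / 0.2) ** 2), (3, 1))
        line = ProfileLine((0.0, 0.01), (4.0, 0.01), 0.005)
        m = fwhm_diameter(img, grid, line)
        assert m.fwhm_mm == pytest.approx(0.4709640090061899, abs=0.01)

    def test_crossings_bracket_peak(self):
        grid = self._grid()
        x = grid.x_mm
        img = np.tile(np.exp(-0.5 * ((x - 0.8) / 0.1) ** 2), (3, 1))
        m = fwhm_diameter(img, grid, ProfileLine((0.0, 0.02), (1.6, 0.02), 0.01))
        assert m.crossings_mm[0] < 0.8 < m.crossings_mm[1]

    def test_flat_profile_rejected(self):
        grid = self._grid()
        with pytest.raises(ValueError):
            fwhm_diameter(np.ones(grid.shape), grid,
                          ProfileLine((0.0, 0.02), (1.6, 0.02), 0.01))

    def test_oversized_step_rejected(self):
        grid = self._grid()
        with pytest.raises(ValueError):
            sample_profile(np.ones(grid.shape), grid,
                           ProfileLine((0.0, 0.02), (1.6, 0.02), 0.5))

    @pytest.mark.parametrize("d_mm", [0.25, 0.5, 1.0])
    def test_disc_diameter_recovered_within_one_pitch(self, d_mm):
        """Discs rendered directly on the grid (no acoustics) are measured
        to within one pixel pitch."""
        pitch = 0.05
        grid = ImageGrid((61, 61), pitch, origin_mm=(-1.5, -1.5))
        xx, zz = grid.mesh()
        img = ((xx ** 2 + zz ** 2) <= (d_mm / 2) ** 2).astype(float)
        line = ProfileLine((-1.5, 0.0), (1.5, 0.0), 0.01)
        m = fwhm_diameter(img, grid, line)
        assert abs(m.fwhm_mm - d_mm) <= pitch + 1e-9


class TestDiameterRegression:
    def test_perfect_agreement_gives_unit_r2(self):
        pairs = [(0.2, 0.2), (0.5, 0.5), (0.9, 0.9)]
        assert diameter_regression(pairs)["r2"] == pytest.approx(1.0)

    def test_four_printed_case_pairs_match_frozen_oracle(self):
        """OLS R^2 for the four fully tabulated vessel pairs, frozen from an
        independent closed-form computation."""
        pairs = [(0.3, 0.33), (0.4, 0.45), (0.9, 0.86), (0.3, 0.32)]
        fit = diameter_regression(pairs)
        assert fit["r2"] == pytest.approx(0.9949023917935835, abs=1e-12)
        assert fit["slope"] == pytest.approx(1.129533678756477, abs=1e-12)

    def test_constant_estimates_give_nonpositive_r2(self):
        fit = diameter_regression([(0.5, 0.2), (0.5, 0.6), (0.5, 1.0)])
        assert fit["r2"] <= 0 or fit["r2"] == 0.0

    def test_constant_truth_rejected(self):
        with pytest.raises(ValueError):
            diameter_regression([(0.3, 0.5), (0.4, 0.5)])

    def test_matches_closed_form_ols_on_random_datasets(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(3, 12)
            true = rng.uniform(0.1, 1.0, n)
            if np.allclose(true, true[0]):
                continue
            est = true + rng.normal(0, 0.1, n)
            fit = diameter_regression(np.column_stack([est, true]))
            # independent closed form
            sxy = np.sum((true - true.mean()) * (est - est.mean()))
            sxx = np.sum((true - true.mean()) ** 2)
            pred = est.mean() + sxy / sxx * (true - true.mean())
            r2 = 1 - np.sum((est - pred) ** 2) / np.sum((est - est.mean()) ** 2)
            assert fit["r2"] == pytest.approx(r2, abs=1e-10)


class TestGroupComparison:
    def test_identical_groups_not_rejected(self):
        g = [0.7, 0.72, 0.68, 0.71]
        res = compare_groups(g, g, alpha=0.05)
        assert not res.reject and res.p_value > 0.05

    def test_welch_variant_available(self):
        rng = np.random.default_rng(1)
        res = compare_groups(rng.normal(0.7, 0.05, 16),
                             rng.normal(0.5, 0.05, 11), test="welch")
        assert res.test == "welch" and res.reject

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([0.5, 0.6], [0.5, 0.6, 0.7])
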