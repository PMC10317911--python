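"""Linear NNLS and blind regularized-NMF spectral unmixing."""
import numpy as np
import pytest

from msot import blind_unmix, linear_unmix, match_components, relative_mse
from msot.phantom import ImageGrid
from msot.reconstruct import MultispectralImage
from msot.spectra import ReferenceMatrix, WavelengthGrid
from msot.unmix import UnmixResult


def _image_from_pixels(X, wl, shape):
    """Build a MultispectralImage whose pixel spectra are the rows of X."""
    data = X.T.reshape(len(wl), *shape)
    return MultispectralImage(data=data, grid=wl,
                              image_grid=ImageGrid(shape, 0.1))


class TestLinearUnmix:
    def test_pure_scaled_column_recovered_exactly(self, wl6, refs6):
        shape = (4, 4)
        X = np.tile(2.0 * refs6.column("hbo2"), (16, 1))
        res = linear_unmix(_image_from_pixels(X, wl6, shape), refs6)
        i = res.component_names.index("hbo2")
        np.testing.assert_allclose(res.coefficient_maps[i], 2.0, atol=1e-8)
        others = np.delete(res.coefficient_maps, i, axis=0)
        assert np.abs(others).max() <= 1e-8
        assert res.rel_mse_percent <= 1e-10

    def test_two_component_mixture_recovered(self, wl6, refs6):
        X = np.tile(refs6.column("hbo2") + refs6.column("hbr"), (9, 1))
        res = linear_unmix(_image_from_pixels(X, wl6, (3, 3)), refs6)
        for name in ("hbo2", "hbr"):
            i = res.component_names.index(name)
            np.testing.assert_allclose(res.coefficient_maps[i], 1.0, atol=1e-6)

    def test_zero_stack_gives_zero_coefficients(self, wl6, refs6):
        res = linear_unmix(_image_from_pixels(np.zeros((4, 6)), wl6, (2, 2)),
                           refs6)
        assert not np.any(res.coefficient_maps)
        assert res.rel_mse_percent == 0.0

    def test_wavelength_mismatch_rejected(self, wl6, refs14):
        X = np.ones((4, 6))
        with pytest.raises(ValueError):
            linear_unmix(_image_from_pixels(X, wl6, (2, 2)), refs14)

    def test_scale_indifference_of_downstream_so2(self, wl6, refs6):
        from msot import so2_map
        spec = 0.7 * refs6.column("hbo2") + 0.3 * refs6.column("hbr")
        X = np.tile(spec, (4, 1))
        img1 = _image_from_pixels(X, wl6, (2, 2))
        img5 = _image_from_pixels(5.0 * X, wl6, (2, 2))
        r1, r5 = linear_unmix(img1, refs6), linear_unmix(img5, refs6)
        np.testing.assert_allclose(r5.coefficient_maps,
                                   5.0 * r1.coefficient_maps, atol=1e-8)
        i_o = r1.component_names.index("hbo2")
        i_r = r1.component_names.index("hbr")
        s1 = so2_map(r1.coefficient_maps[i_o], r1.coefficient_maps[i_r])
        s5 = so2_map(r5.coefficient_maps[i_o], r5.coefficient_maps[i_r])
        np.testing.assert_allclose(s1.data, s5.data, atol=1e-10)

    def test_spectral_crosstalk_mechanism(self, wl6, refs6):
        """Unmixing a true HbO2 spectrum against a basis whose oxy component
        is deficient above 850 nm pushes signal into the lipid channel."""
        deficient = refs6.column("hbo2").copy()
        deficient[np.array(wl6.wavelengths) > 850] *= 0.3
        basis = ReferenceMatrix(
            grid=wl6, chromophores=("hbo2", "lipid"),
            matrix=np.column_stack([deficient, refs6.column("lipid")]))
        X = np.tile(refs6.column("hbo2"), (4, 1))
        res = linear_unmix(_image_from_pixels(X, wl6, (2, 2)), basis)
        i_lip = res.component_names.index("lipid")
        assert res.coefficient_maps[i_lip].min() > 0


class TestBlindUnmix:
    def test_rank_one_data_recovered(self, wl6):
        from msot.spectra import cosine_similarity
        rng = np.random.default_rng(0)
        spec = np.array([1.0, 2.5, 1.2, 0.3, 0.8, 1.9])
        amp = rng.random(25)
        X = np.outer(amp, spec)
        res = blind_unmix(_image_from_pixels(X, wl6, (5, 5)), k=1, seed=0)
        assert cosine_similarity(res.spectra[:, 0], spec) >= 0.999

    def test_deterministic_per_seed(self, wl6):
        rng = np.random.default_rng(1)
        X = rng.random((16, 6))
        img = _image_from_pixels(X, wl6, (4, 4))
        a = blind_unmix(img, k=3, alpha_l1=1e-3, beta_l2=1e-3, seed=11)
        b = blind_unmix(img, k=3, alpha_l1=1e-3, beta_l2=1e-3, seed=11)
        np.testing.assert_array_equal(a.coefficient_maps, b.coefficient_maps)
        np.testing.assert_array_equal(a.spectra, b.spectra)

    def test_factors_nonnegative_and_objective_monotone(self, wl6):
        rng = np.random.default_rng(2)
        X = rng.random((36, 6))
        res = blind_unmix(_image_from_pixels(X, wl6, (6, 6)), k=4,
                          alpha_l1=1e-2, beta_l2=1e-2, seed=5)
        assert res.coefficient_maps.min() >= 0
        assert res.spectra.min() >= 0
        obj = np.asarray(res.objectives)
        assert np.all(np.diff(obj) <= 1e-9 * obj[0])

    def test_k_exceeding_wavelengths_rejected(self, wl6):
        img = _image_from_pixels(np.ones((4, 6)), wl6, (2, 2))
        with pytest.raises(ValueError):
            blind_unmix(img, k=7)


class TestRelativeMse:
    def _img_and_result(self, wl6, scale):
        m = np.array([1.0, 2.0, 3.0, 4.0])
        s = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        X = np.outer(m, s)
        img = _image_from_pixels(X, wl6, (2, 2))
        res = UnmixResult(coefficient_maps=(scale * m).reshape(1, 2, 2),
                          spectra=s.reshape(-1, 1),
                          rel_mse_percent=0.0, mode="blind")
        return img, res

    def test_closed_forms(self, wl6):
        img, exact = self._img_and_result(wl6, 1.0)
        assert relative_mse(img, exact) == pytest.approx(0.0, abs=1e-12)
        _, half = self._img_and_result(wl6, 0.5)
        assert relative_mse(img, half) == pytest.approx(25.0)
        _, zero = self._img_and_result(wl6, 0.0)
        assert relative_mse(img, zero) == pytest.approx(100.0)

    def test_all_zero_stack_rejected(self, wl6):
        img = _image_from_pixels(np.zeros((4, 6)), wl6, (2, 2))
        _, res = self._img_and_result(wl6, 1.0)
        with pytest.raises(ValueError):
            relative_mse(img, res)


class TestComponentMatching:
    def _blind_result(self, spectra, wl):
        k = spectra.shape[1]
        return UnmixResult(coefficient_maps=np.ones((k, 1, 1)),
                           spectra=spectra, rel_mse_percent=0.0, mode="blind")

    def test_identity_and_permutation_recovered(self, wl6, refs6):
        res = self._blind_result(refs6.matrix.copy(), wl6)
        m = match_components(res, refs6)
        assert m.assignment == {n: i for i, n in enumerate(refs6.chromophores)}
        assert all(s == pytest.approx(1.0) for s in m.scores.values())
        perm = [2, 0, 5, 1, 4, 3]
        res_p = self._blind_result(refs6.matrix[:, perm], wl6)
        m_p = match_components(res_p, refs6)
        for i, name in enumerate(refs6.chromophores):
            assert m_p.assignment[name] == perm.index(i)

    def test_noisy_component_matched_with_high_score(self, wl6, refs6):
        rng = np.random.default_rng(4)
        hbo2 = refs6.column("hbo2")
        noisy = np.abs(hbo2 + rng.normal(0, 0.1 * np.linalg.norm(hbo2) /
                                         np.sqrt(len(hbo2)), hbo2.shape))
        spectra = np.column_stack([noisy] + [refs6.matrix[:, i]
                                             for i in range(1, 6)])
        m = match_components(self._blind_result(spectra, wl6), refs6)
        assert m.assignment["hbo2"] == 0
        assert m.scores["hbo2"] >= 0.98

    def test_linear_mode_rejected(self, wl6, refs6):
        res = UnmixResult(coefficient_maps=np.ones((6, 1, 1)),
                          spectra=refs6.matrix, rel_mse_percent=0.0,
                          mode="linear")
        with pytest.raises(ValueError):
            match_components(res, refs6)
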