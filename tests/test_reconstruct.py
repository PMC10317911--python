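"""Model-based inversion: solver contracts, baseline, L-curve."""
import numpy as np
import pytest
from scipy.optimize import nnls

from msot import (ArrayGeometry, ImpulseResponse, backproject, model_based,
                  reconstruct_stack, select_lambda_lcurve)
from msot.geometry import time_window_for_grid
from msot.phantom import ImageGrid
from msot.forward import build_system_matrix
from msot.reconstruct import ReconConfig
from msot.simulate import MultispectralSinogram
from msot.spectra import WavelengthGrid


class TestModelBased:
    def test_matches_dense_nnls_oracle_at_zero_penalty(self, small_system,
                                                       disc_image,
                                                       disc_sinogram):
        """With lambda -> 0 on a noiseless consistent system the solver must
        agree with an independent dense NNLS solve."""
        res = model_based(disc_sinogram, small_system,
                          ReconConfig(lambda_reg=0.0, max_iter=300, tol=1e-12,
                                      debias_iter=1500, debias_passes=3))
        dense = small_system.as_dense()
        x_ref, _ = nnls(dense, disc_sinogram.ravel(),
                        maxiter=100 * dense.shape[1])
        err = np.linalg.norm(res.image.ravel() - x_ref) / np.linalg.norm(x_ref)
        assert err <= 1e-3

    def test_images_are_nonnegative_even_on_noisy_data(self, small_system,
                                                       disc_sinogram):
        rng = np.random.default_rng(0)
        noisy = disc_sinogram + rng.normal(
            0, 0.05 * np.abs(disc_sinogram).max(), disc_sinogram.shape)
        res = model_based(noisy, small_system,
                          ReconConfig(lambda_rel=1e-3, max_iter=60))
        assert res.image.min() >= 0

    def test_objective_monotone_over_accepted_iterates(self, small_system,
                                                       disc_sinogram):
        res = model_based(disc_sinogram, small_system,
                          ReconConfig(lambda_rel=1e-3, max_iter=80,
                                      debias=False))
        obj = np.asarray(res.objectives)
        assert np.all(np.diff(obj) <= 1e-9 * obj[0])

    def test_huge_penalty_collapses_to_zero_image(self, small_system,
                                                  disc_sinogram):
        res = model_based(disc_sinogram, small_system,
                          ReconConfig(lambda_reg=1e12, max_iter=30,
                                      debias=False))
        assert np.abs(res.image).max() <= 1e-8
        assert res.residual_norm == pytest.approx(
            np.linalg.norm(disc_sinogram), rel=1e-6)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            ReconConfig(lambda_reg=-1.0)

    def test_spectral_shape_preserved_without_noise(self, refs6):
        """Reconstructed vessel spectrum equals mu_a * Phi up to one global
        constant on a noiseless coloured phantom (<= 5% relative error)."""
        from msot import build_phantom, compute_mu_a, simulate_stack
        from msot.fluence import FluenceModel, compute_fluence
        wl = WavelengthGrid((730, 800, 900, 970))
        from msot.spectra import load_reference_spectra
        refs = load_reference_spectra(["hbo2", "hbr", "h2o", "lipid",
                                       "collagen", "melanin"], wl)
        scene = {"shape": (36, 36), "pitch_mm": 0.1, "origin_mm": (-1.75, 18.25),
                 "background": {"h2o": 0.8},
                 "vessels": [{"center_mm": (0.0, 20.0), "diameter_mm": 0.5,
                              "so2": 1.0}]}
        ph = build_phantom(scene)
        geom = time_window_for_grid(ArrayGeometry(n_elements=96),
                                    ph.grid.pixel_centers())
        ir = ImpulseResponse(sampling_rate_mhz=geom.sampling_rate_mhz)
        A = build_system_matrix(geom, ph.grid, ir=ir)
        sino = simulate_stack(ph, wl, refs, system=A)
        img = reconstruct_stack(sino, A, ReconConfig(lambda_rel=1e-3,
                                                     max_iter=120))
        mu = compute_mu_a(ph, wl, refs)
        phi = compute_fluence(mu, ph.grid.pitch_mm, FluenceModel())
        iz = ph.grid.nz // 2
        ix = ph.grid.nx // 2
        truth = mu[:, iz, ix] * phi[:, iz, ix]
        recon = img.data[:, iz, ix]
        ratio = recon / truth
        assert np.abs(ratio / ratio.mean() - 1).max() <= 0.05


class TestBackprojection:
    def test_zero_sinogram_gives_zero_image(self, small_geometry, small_grid):
        img = backproject(np.zeros((small_geometry.n_elements,
                                    small_geometry.n_samples)),
                          small_geometry, small_grid)
        assert not np.any(img)

    def test_point_source_localised_within_two_pixels(self, small_grid):
        geom = time_window_for_grid(ArrayGeometry(n_elements=96),
                                    small_grid.pixel_centers())
        ir = ImpulseResponse(sampling_rate_mhz=geom.sampling_rate_mhz)
        A = build_system_matrix(geom, small_grid, ir=ir)
        p0 = np.zeros(small_grid.shape)
        p0[12, 12] = 1.0
        img = backproject(np.abs(A.matvec(p0)), geom, small_grid)
        peak = np.unravel_index(np.argmax(np.abs(img)), img.shape)
        assert abs(peak[0] - 12) <= 2 and abs(peak[1] - 12) <= 2

    def test_left_right_symmetry(self, small_grid):
        geom = time_window_for_grid(ArrayGeometry(n_elements=32),
                                    small_grid.pixel_centers())
        rng = np.random.default_rng(3)
        sino = rng.standard_normal((32, geom.n_samples))
        a = backproject(sino[::-1], geom, small_grid)
        b = backproject(sino, geom, small_grid)[:, ::-1]
        np.testing.assert_allclose(a, b, atol=1e-10 * np.abs(b).max())


class TestLambdaSelection:
    def test_lcurve_residual_monotone_and_selection_avoids_oversmoothing(
            self, small_system, disc_image, disc_sinogram):
        """Residual norm grows with lambda along the curve, and the
        maximum-curvature pick is an interior weight whose reconstruction
        beats the over-regularised endpoint on ground-truth RMSE."""
        rng = np.random.default_rng(1)
        noisy = disc_sinogram + rng.normal(
            0, 0.1 * np.sqrt(np.mean(disc_sinogram ** 2)),
            disc_sinogram.shape)
        scale = float(np.abs(small_system.rmatvec(noisy)).max())
        grid_l = [scale * v for v in (1e-5, 1e-4, 1e-3, 1e-2, 1e-1)]
        cfg = ReconConfig(max_iter=150, debias=False)
        lam, curve = select_lambda_lcurve(noisy, small_system, grid_l, cfg)
        res_norms = [c[1] for c in curve]
        assert all(res_norms[i + 1] >= res_norms[i] - 1e-9 * res_norms[i]
                   for i in range(len(res_norms) - 1))
        assert grid_l[0] < lam < grid_l[-1]     # interior pick
        def rmse(l):
            r = model_based(noisy, small_system,
                            ReconConfig(lambda_reg=l, max_iter=150,
                                        debias=False))
            return np.linalg.norm(r.image - disc_image)
        assert rmse(lam) < rmse(grid_l[-1])

    def test_single_element_grid_returned(self, small_system, disc_sinogram):
        lam, curve = select_lambda_lcurve(disc_sinogram, small_system, [0.5],
                                          ReconConfig(max_iter=5, debias=False))
        assert lam == 0.5 and len(curve) == 1

    def test_unsorted_grid_rejected(self, small_system, disc_sinogram):
        with pytest.raises(ValueError):
            select_lambda_lcurve(disc_sinogram, small_system, [1.0, 0.1])


class TestReconstructStack:
    def _stack(self, sino, n, geometry):
        data = np.stack([sino] * n)
        wl = WavelengthGrid((700, 800, 900)[:n])
        return MultispectralSinogram(data=data, grid=wl, geometry=geometry)

    def test_duplicate_wavelengths_give_identical_images(self, small_system,
                                                         small_geometry,
                                                         disc_sinogram):
        stack = self._stack(disc_sinogram, 3, small_geometry)
        img = reconstruct_stack(stack, small_system,
                                ReconConfig(lambda_rel=1e-3, max_iter=40,
                                            debias=False))
        np.testing.assert_array_equal(img.data[0], img.data[1])
        np.testing.assert_array_equal(img.data[0], img.data[2])

    def test_zero_penalty_scales_linearly_across_wavelengths(
            self, small_system, small_geometry, disc_sinogram):
        data = np.stack([disc_sinogram, 2.0 * disc_sinogram])
        stack = MultispectralSinogram(data=data,
                                      grid=WavelengthGrid((700, 800)),
                                      geometry=small_geometry)
        img = reconstruct_stack(stack, small_system,
                                ReconConfig(lambda_reg=0.0, max_iter=150,
                                            tol=1e-10))
        np.testing.assert_allclose(img.data[1], 2.0 * img.data[0],
                                   atol=1e-4 * img.data[1].max())

    def test_provenance_records_per_wavelength_residuals(self, small_system,
                                                         small_geometry,
                                                         disc_sinogram):
        stack = self._stack(disc_sinogram, 2, small_geometry)
        img = reconstruct_stack(stack, small_system,
                                ReconConfig(lambda_rel=1e-3, max_iter=20,
                                            debias=False))
        assert len(img.provenance["residual_norms"]) == 2
        assert img.provenance["lambda_reg"] > 0
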