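"""Sparsifying transforms for the L1 reconstruction penalty.

`ShearletSystem` is a cone-adapted directional multiscale frame built from
smooth frequency-domain windows: log-radial octave bands split into
orientation wedges whose count doubles per scale (shearlet-style parabolic
anisotropy in the angular resolution), plus a residual low-pass. The windows
are normalised so that sum_i |Psi_i(xi)|^2 = 1 exactly, making the system a
Parseval tight frame: synthesis(analysis(x)) == x and the coefficient energy
equals the image energy to machine precision.

`WaveletSystem` is the separable orthonormal fallback (PyWavelets) selected
through the same factory for configurations that prefer a non-redundant
transform.
"""
from __future__ import annotations

import numpy as np
import pywt

__all__ = ["ShearletSystem", "WaveletSystem", "make_transform"]


class ShearletSystem:
    """Frequency-domain directional Parseval frame on a fixed image shape."""

    def __init__(self, shape, n_scales: int = 3, base_directions: int = 4,
                 angular_sharpness: float = 0.7):
        nz, nx = shape
        if nz < 8 or nx < 8:
            raise ValueError("image too small for the directional system")
        self.shape = (nz, nx)
        self.n_scales = int(n_scales)
        fz = np.fft.fftfreq(nz)[:, None]
        fx = np.fft.fftfreq(nx)[None, :]
        rho = np.sqrt(fz ** 2 + fx ** 2)
        theta = np.mod(np.arctan2(fz, fx), np.pi)   # orientation, pi-periodic

        windows = []
        self.scale_of_band = []
        with np.errstate(divide="ignore"):
            log_rho = np.log2(np.where(rho > 0, rho, 1e-30))
        for j in range(self.n_scales):
            rho_j = 0.25 * 2.0 ** (-j)
            radial = np.exp(-0.5 * ((log_rho - np.log2(rho_j)) / 0.6) ** 2)
            n_dir = base_directions * 2 ** j
            sigma = angular_sharpness * np.pi / n_dir
            for k in range(n_dir):
                theta_k = k * np.pi / n_dir
                d = np.mod(theta - theta_k + np.pi / 2, np.pi) - np.pi / 2
                windows.append(radial * np.exp(-0.5 * (d / sigma) ** 2))
                self.scale_of_band.append(j)
        sigma_lo = 0.25 * 2.0 ** (-(self.n_scales - 1)) / 2.0
        windows.append(np.exp(-0.5 * (rho / sigma_lo) ** 2))
        self.scale_of_band.append(self.n_scales)

        stack = np.stack(windows)
        # enforce exact xi -> -xi symmetry (the aliased Nyquist line is
        # orientation-ambiguous) so coefficients of real images are real
        mirror = stack[:, (-np.arange(nz)) % nz][:, :, (-np.arange(nx)) % nx]
        stack = 0.5 * (stack + mirror)
        norm = np.sqrt((stack ** 2).sum(axis=0))
        self.filters = stack / norm            # sum of squares == 1 everywhere
        self.n_bands = self.filters.shape[0]

    def analysis(self, image: np.ndarray) -> np.ndarray:
        if image.shape != self.shape:
            raise ValueError("image shape incompatible with the system")
        F = np.fft.fft2(image)
        return np.real(np.fft.ifft2(F[None, :, :] * self.filters))

    def synthesis(self, coeffs: np.ndarray) -> np.ndarray:
        if coeffs.shape != (self.n_bands, *self.shape):
            raise ValueError("coefficient stack incompatible with the system")
        C = np.fft.fft2(coeffs, axes=(-2, -1))
        return np.real(np.fft.ifft2((C * self.filters).sum(axis=0)))

    @property
    def n_coefficients(self) -> int:
        return self.n_bands * self.shape[0] * self.shape[1]


class WaveletSystem:
    """Orthonormal separable wavelet transform with the same interface."""

    def __init__(self, shape, n_scales: int = 3, wavelet: str = "db4"):
        self.shape = tuple(shape)
        self.wavelet = wavelet
        self.n_scales = min(int(n_scales),
                            pywt.dwtn_max_level(shape, wavelet))
        coeffs = pywt.wavedec2(np.zeros(shape), wavelet,
                               level=self.n_scales, mode="periodization")
        _, self._slices = pywt.coeffs_to_array(coeffs)

    def analysis(self, image: np.ndarray) -> np.ndarray:
        if image.shape != self.shape:
            raise ValueError("image shape incompatible with the system")
        coeffs = pywt.wavedec2(image, self.wavelet, level=self.n_scales,
                               mode="periodization")
        arr, _ = pywt.coeffs_to_array(coeffs)
        return arr

    def synthesis(self, arr: np.ndarray) -> np.ndarray:
        coeffs = pywt.array_to_coeffs(arr, self._slices, output_format="wavedec2")
        out = pywt.waverec2(coeffs, self.wavelet, mode="periodization")
        return out[: self.shape[0], : self.shape[1]]

    @property
    def n_coefficients(self) -> int:
        return int(np.prod(self.shape))


def make_transform(shape, kind: str = "shearlet", n_scales: int = 3):
    if kind == "shearlet":
        return ShearletSystem(shape, n_scales=n_scales)
    if kind == "wavelet":
        return WaveletSystem(shape, n_scales=n_scales)
    raise ValueError(f"unknown transform kind {kind!r}")
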