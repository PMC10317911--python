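"""Discrete 2-D optoacoustic forward operator for the concave array.

The measurement model is the standard circular-integral one: each image pixel
deposits its initial pressure onto the time sample corresponding to its
flight time to an element (linear interpolation between the two neighbouring
samples, 1/d geometrical spreading), the per-channel trace is differentiated
in time (N-shaped optoacoustic signature), and finally convolved with the
band-limited transducer impulse response. The operator is linear and
wavelength-independent; the same discretisation backs both the simulator and
the model-based inversion, exposed either matrix-free (`forward_project`) or
as a sparse `SystemMatrix` with an exact adjoint.
"""
from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.signal import fftconvolve

from .geometry import ArrayGeometry, ImpulseResponse
from .phantom import ImageGrid

__all__ = ["SystemMatrix", "build_system_matrix", "forward_project",
           "apply_impulse_response", "temporal_derivative"]


def _sample_coords(geometry: ArrayGeometry, grid: ImageGrid):
    """Flight-time sample coordinate and 1/d weight for every (element, pixel)."""
    pos = geometry.element_positions                    # (Ne, 2)
    centers = grid.pixel_centers()                      # (Np, 2)
    d = np.sqrt(((centers[None, :, :] - pos[:, None, :]) ** 2).sum(-1))
    off = geometry.time_of_flight_offset_us()
    s = (d / geometry.sos_mm_us + off - geometry.t0_us) * geometry.sampling_rate_mhz
    w = grid.pitch_mm ** 2 / np.maximum(d, 0.5 * grid.pitch_mm)
    return s, w


def _check_window(s: np.ndarray, n_samples: int):
    if s.min() < 0 or s.max() >= n_samples - 1:
        raise ValueError(
            "image grid extends beyond the recordable time window; enlarge "
            "n_samples / adjust t0 (see geometry.time_window_for_grid)")


def temporal_derivative(g: np.ndarray, fs_mhz: float, adjoint: bool = False) -> np.ndarray:
    """Central-difference time derivative along the last axis (zero boundary).

    The adjoint is exactly the negated derivative, which `adjoint=True` applies.
    """
    out = np.zeros_like(g)
    out[..., :-1] += g[..., 1:]
    out[..., 1:] -= g[..., :-1]
    out *= 0.5 * fs_mhz
    return -out if adjoint else out


def _convolve_same(traces: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    shape = [1] * traces.ndim
    shape[-1] = kernel.size
    return fftconvolve(traces, kernel.reshape(shape), mode="same", axes=-1)


def apply_impulse_response(sinogram: np.ndarray, ir: ImpulseResponse,
                           adjoint: bool = False) -> np.ndarray:
    """Per-channel convolution with the band-limited (zero-mean) kernel."""
    h = ir.kernel
    if h.size > sinogram.shape[-1]:
        raise ValueError("impulse-response kernel longer than the trace")
    return _convolve_same(sinogram, h[::-1] if adjoint else h)


class SystemMatrix:
    """Sparse discrete forward operator A = (impulse response) o d/dt o (ring sum).

    Supports matvec/rmatvec (exact adjoint pair), densification for small
    grids, and carries the grid/geometry metadata the reconstruction needs.
    """

    def __init__(self, geometry: ArrayGeometry, grid: ImageGrid,
                 ir: ImpulseResponse | None = None, use_derivative: bool = True):
        self.geometry = geometry
        self.grid = grid
        self.ir = ir
        self.use_derivative = use_derivative
        s, w = _sample_coords(geometry, grid)
        _check_window(s, geometry.n_samples)
        ne, npix = s.shape
        nt = geometry.n_samples
        i0 = np.floor(s).astype(np.int64)
        frac = s - i0
        rows = np.concatenate([(np.arange(ne)[:, None] * nt + i0).ravel(),
                               (np.arange(ne)[:, None] * nt + i0 + 1).ravel()])
        cols = np.tile(np.tile(np.arange(npix), ne), 2)
        vals = np.concatenate([(w * (1 - frac)).ravel(), (w * frac).ravel()])
        self._ring = sparse.csr_matrix((vals, (rows, cols)), shape=(ne * nt, npix))
        self._kernel = None if ir is None else ir.kernel

    @property
    def shape(self):
        return self._ring.shape

    @property
    def n_elements(self):
        return self.geometry.n_elements

    @property
    def n_samples(self):
        return self.geometry.n_samples

    def matvec(self, x: np.ndarray) -> np.ndarray:
        """Image (nz, nx) or flat vector -> sinogram (n_elements, n_samples)."""
        g = (self._ring @ np.ravel(x)).reshape(self.n_elements, self.n_samples)
        if self.use_derivative:
            g = temporal_derivative(g, self.geometry.sampling_rate_mhz)
        if self._kernel is not None:
            g = _convolve_same(g, self._kernel)
        return g

    def rmatvec(self, y: np.ndarray) -> np.ndarray:
        """Adjoint: sinogram -> image (nz, nx)."""
        g = np.asarray(y, dtype=float).reshape(self.n_elements, self.n_samples)
        if self._kernel is not None:
            g = _convolve_same(g, self._kernel[::-1])
        if self.use_derivative:
            g = temporal_derivative(g, self.geometry.sampling_rate_mhz, adjoint=True)
        return (self._ring.T @ g.ravel()).reshape(self.grid.shape)

    def as_dense(self) -> np.ndarray:
        """Dense (n_data, n_pixels) matrix; small grids only."""
        npix = self.grid.nz * self.grid.nx
        cols = np.empty((self.shape[0], npix))
        e = np.zeros(npix)
        for j in range(npix):
            e[j] = 1.0
            cols[:, j] = self.matvec(e).ravel()
            e[j] = 0.0
        return cols


def build_system_matrix(geometry: ArrayGeometry, grid: ImageGrid,
                        ir: ImpulseResponse | None = None,
                        use_derivative: bool = True) -> SystemMatrix:
    return SystemMatrix(geometry, grid, ir=ir, use_derivative=use_derivative)


def forward_project(p0: np.ndarray, geometry: ArrayGeometry, grid: ImageGrid,
                    ir: ImpulseResponse | None = None,
                    use_derivative: bool = True) -> np.ndarray:
    """Matrix-free forward projection of a single-wavelength p0 map.

    Direct accumulation of the same discretisation `SystemMatrix` assembles;
    the two paths agree to numerical precision.
    """
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != grid.shape:
        raise ValueError("p0 shape does not match the image grid")
    s, w = _sample_coords(geometry, grid)
    _check_window(s, geometry.n_samples)
    ne = geometry.n_elements
    nt = geometry.n_samples
    i0 = np.floor(s).astype(np.int64)
    frac = s - i0
    contrib = w * p0.ravel()[None, :]
    flat = np.zeros(ne * nt)
    base = np.arange(ne)[:, None] * nt
    np.add.at(flat, (base + i0).ravel(), (contrib * (1 - frac)).ravel())
    np.add.at(flat, (base + i0 + 1).ravel(), (contrib * frac).ravel())
    g = flat.reshape(ne, nt)
    if use_derivative:
        g = temporal_derivative(g, geometry.sampling_rate_mhz)
    if ir is not None:
        g = apply_impulse_response(g, ir)
    return g
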