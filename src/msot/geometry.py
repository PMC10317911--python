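"""Detection geometry and transducer impulse response of the hand-held probe.

The scanner's concave array has 256 elements spanning 125 degrees on an arc of
radius 40 mm, with a 3.4 MHz centre frequency and 60% (-6 dB) fractional
bandwidth. Coordinates: x lateral, z depth (0 at the probe face, increasing
into tissue, mm everywhere). The arc's centre of curvature sits on the z axis
at ``focus_depth_mm`` so the imaging plane around the focus is well inside the
aperture. Times are in microseconds, frequencies in MHz, so the speed of
sound is carried in mm/us (1.5 mm/us = 1500 m/s).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ArrayGeometry", "ImpulseResponse", "time_window_for_grid"]


@dataclass(frozen=True)
class ArrayGeometry:
    """Concave detection arc + temporal sampling of the data acquisition."""

    n_elements: int = 256
    coverage_deg: float = 125.0
    radius_mm: float = 40.0
    focus_depth_mm: float = 20.0
    sampling_rate_mhz: float = 40.0
    n_samples: int = 2030
    t0_us: float = 0.0
    sos_mm_us: float = 1.5          # effective speed of sound
    sos_couplant_mm_us: float | None = None  # optional couplant/tissue pair
    couplant_path_mm: float = 0.0   # path length inside couplant, per element

    def __post_init__(self):
        if self.n_elements < 2:
            raise ValueError("need at least 2 elements")
        if not (0 < self.coverage_deg <= 360):
            raise ValueError("coverage must be in (0, 360] degrees")
        if self.radius_mm <= 0 or self.sampling_rate_mhz <= 0 or self.n_samples < 2:
            raise ValueError("invalid geometry parameters")

    @property
    def element_positions(self) -> np.ndarray:
        """(n_elements, 2) array of (x, z) positions in mm, equispaced on the arc."""
        half = np.deg2rad(self.coverage_deg) / 2.0
        phi = np.linspace(-half, half, self.n_elements)
        cx, cz = 0.0, self.focus_depth_mm
        x = cx + self.radius_mm * np.sin(phi)
        z = cz - self.radius_mm * np.cos(phi)
        return np.column_stack([x, z])

    @property
    def dt_us(self) -> float:
        return 1.0 / self.sampling_rate_mhz

    @property
    def times_us(self) -> np.ndarray:
        return self.t0_us + np.arange(self.n_samples) * self.dt_us

    def time_of_flight_offset_us(self) -> float:
        """Extra delay from a couplant/tissue speed-of-sound pair.

        Refraction is not modelled; a distinct couplant speed only shifts
        arrival times by a per-element constant (straight-ray path of length
        ``couplant_path_mm`` traversed at the couplant speed instead of the
        tissue speed).
        """
        if self.sos_couplant_mm_us is None or self.couplant_path_mm == 0.0:
            return 0.0
        return self.couplant_path_mm * (
            1.0 / self.sos_couplant_mm_us - 1.0 / self.sos_mm_us
        )

    def replace(self, **kw) -> "ArrayGeometry":
        from dataclasses import replace
        return replace(self, **kw)


@dataclass(frozen=True)
class ImpulseResponse:
    """Band-limited transducer response: Gaussian band around 3.4 MHz.

    The -6 dB (half-amplitude) band edges sit at f_c * (1 +/- 0.3) for the
    default 60% fractional bandwidth. The kernel is zero-mean (no DC
    sensitivity) and normalised to unit peak gain in band.
    """

    center_frequency_mhz: float = 3.4
    fractional_bandwidth: float = 0.60   # -6 dB, two-sided
    sampling_rate_mhz: float = 40.0
    n_sigma: float = 4.0

    def __post_init__(self):
        if self.center_frequency_mhz <= 0 or not (0 < self.fractional_bandwidth < 2):
            raise ValueError("invalid impulse-response parameters")
        if self.center_frequency_mhz >= self.sampling_rate_mhz / 2:
            raise ValueError("centre frequency above Nyquist")

    @property
    def sigma_f_mhz(self) -> float:
        # half-amplitude half-width = 0.5 * fbw * fc ; gaussian drops to 1/2
        # at sqrt(2 ln 2) sigma
        half_width = 0.5 * self.fractional_bandwidth * self.center_frequency_mhz
        return half_width / np.sqrt(2.0 * np.log(2.0))

    @property
    def kernel(self) -> np.ndarray:
        """Odd-length, centred, zero-mean FIR kernel with unit in-band peak gain."""
        sigma_t = 1.0 / (2.0 * np.pi * self.sigma_f_mhz)     # us
        dt = 1.0 / self.sampling_rate_mhz
        half = max(1, int(np.ceil(self.n_sigma * sigma_t / dt)))
        t = (np.arange(-half, half + 1)) * dt
        env = np.exp(-0.5 * (t / sigma_t) ** 2)
        h = env * np.cos(2.0 * np.pi * self.center_frequency_mhz * t)
        # remove residual DC inside the envelope support (keeps compactness)
        h = h - env * (h.sum() / env.sum())
        # unit peak magnitude response
        n_fft = 8192
        gain = np.abs(np.fft.rfft(h, n_fft)).max()
        return h / gain

    def frequency_response(self, freqs_mhz) -> np.ndarray:
        """|H(f)| of the discrete kernel at the requested frequencies."""
        h = self.kernel
        f = np.atleast_1d(np.asarray(freqs_mhz, dtype=float))
        n = np.arange(h.size) - h.size // 2
        ph = np.exp(-2j * np.pi * np.outer(f / self.sampling_rate_mhz, n))
        return np.abs(ph @ h)


def time_window_for_grid(geometry: ArrayGeometry, pixel_xz_mm: np.ndarray,
                         margin_us: float = 1.0) -> ArrayGeometry:
    """Return a copy of ``geometry`` whose time axis covers every
    element-to-pixel flight time for the given pixel centres, plus a margin
    for the impulse-response tails."""
    pos = geometry.element_positions
    d = np.sqrt(((pixel_xz_mm[None, :, :] - pos[:, None, :]) ** 2).sum(-1))
    off = geometry.time_of_flight_offset_us()
    t_lo = d.min() / geometry.sos_mm_us + off - margin_us
    t_hi = d.max() / geometry.sos_mm_us + off + margin_us
    n = int(np.ceil((t_hi - t_lo) * geometry.sampling_rate_mhz)) + 1
    return geometry.replace(t0_us=float(max(t_lo, 0.0)), n_samples=n)
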