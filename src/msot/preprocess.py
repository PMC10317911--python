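"""Signal-domain preprocessing of multispectral sinograms.

Mirrors the acquisition pipeline's raw-data handling: the 1195 nm frames are
discarded (the probe's coupling pad absorbs strongly there, leaving very low
SNR), every trace is band-pass filtered with a zero-phase Butterworth
(0.5–12 MHz), and the denoising stage is an explicit pass-through — the
learned denoiser used on the clinical data is out of scope here and is not
approximated.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .simulate import MultispectralSinogram

__all__ = ["BandpassSpec", "drop_wavelengths", "bandpass", "denoise"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandpassSpec:
    """Butterworth band-pass: 0.5–12 MHz, order 4, applied forward–backward."""

    low_mhz: float = 0.5
    high_mhz: float = 12.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs_mhz: float):
        nyq = fs_mhz / 2.0
        if not (0 < self.low_mhz < self.high_mhz < nyq):
            raise ValueError(
                f"band edges must satisfy 0 < low < high < Nyquist ({nyq} MHz)")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


def drop_wavelengths(stack: MultispectralSinogram,
                     drop=(1195.0,)) -> MultispectralSinogram:
    """Remove acquisitions at the listed wavelengths (order preserved)."""
    drop = [float(v) for v in np.atleast_1d(drop)]
    if not drop:
        return MultispectralSinogram(stack.data.copy(), stack.grid,
                                     stack.geometry, dict(stack.meta))
    new_grid = stack.grid.drop(drop)   # raises on absent wavelengths
    keep = [i for i, w in enumerate(stack.grid.wavelengths) if w not in set(drop)]
    meta = dict(stack.meta)
    meta["dropped_nm"] = sorted(drop)
    return MultispectralSinogram(stack.data[keep], new_grid, stack.geometry, meta)


def bandpass(stack: MultispectralSinogram,
             spec: BandpassSpec = BandpassSpec()) -> MultispectralSinogram:
    """Per-trace Butterworth band-pass; zero-phase so arrival times survive."""
    fs = stack.geometry.sampling_rate_mhz
    spec.validate(fs)
    sos = butter(spec.order, [spec.low_mhz, spec.high_mhz],
                 btype="bandpass", fs=fs, output="sos")
    if spec.zero_phase:
        data = sosfiltfilt(sos, stack.data, axis=-1)
    else:
        from scipy.signal import sosfilt
        data = sosfilt(sos, stack.data, axis=-1)
    meta = dict(stack.meta)
    meta["bandpass_mhz"] = (spec.low_mhz, spec.high_mhz)
    meta["bandpass_order"] = spec.order
    return MultispectralSinogram(np.ascontiguousarray(data), stack.grid,
                                 stack.geometry, meta)


def denoise(stack: MultispectralSinogram,
            method: str = "passthrough") -> MultispectralSinogram:
    """Denoising stage. Only ``"passthrough"`` (identity) is implemented."""
    if method == "passthrough":
        log.info("denoise: learned denoiser not implemented; passing data through")
        meta = dict(stack.meta)
        meta["denoise"] = "passthrough"
        return MultispectralSinogram(stack.data.copy(), stack.grid,
                                     stack.geometry, meta)
    raise NotImplementedError(
        f"denoise method {method!r} is not implemented; use 'passthrough'")
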