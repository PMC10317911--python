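"""Wavelength-dependent light fluence and optoacoustic source generation.

The fluence model is deliberately simple — 1-D depth-only Beer–Lambert decay
with a diffusion-style effective attenuation built from the laterally
averaged absorption of the scene plus a constant reduced scattering term —
because its only job is to produce the *spectral colouring* phenomenology:
wavelengths that water absorbs strongly (970–1000 nm) lose fluence faster
with depth, so deep-vessel spectra recovered without a fluence correction
show a notch there. The reconstruction chain deliberately does NOT undo this
decay; that mismatch is the artefact under study.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import Phantom

__all__ = ["FluenceModel", "compute_fluence", "initial_pressure"]


@dataclass(frozen=True)
class FluenceModel:
    """Depth-only fluence recipe: Phi(lambda, z) from laterally averaged mu_a.

    mu_eff = sqrt(3 * mu_a * (mu_a + mu_s')) with mu_s' constant (cm^-1);
    Phi(z=0) = 1 and Phi decays with the cumulative mu_eff integral.
    """

    mu_s_prime_cm1: float = 10.0

    def effective_attenuation(self, mu_a_cm1: np.ndarray) -> np.ndarray:
        mu_a = np.asarray(mu_a_cm1, dtype=float)
        if np.any(mu_a < 0):
            raise ValueError("mu_a must be non-negative")
        return np.sqrt(3.0 * mu_a * (mu_a + self.mu_s_prime_cm1))


def compute_fluence(mu_a_stack: np.ndarray, pitch_mm: float,
                    model: FluenceModel | None = None) -> np.ndarray:
    """Fluence stack Phi(lambda, z, x), normalised to 1 at the top row.

    The per-wavelength depth profile uses the laterally averaged absorption
    of each row; Phi is constant along x (1-D illumination model) and
    strictly positive and non-increasing with depth.
    """
    if model is None:
        model = FluenceModel()
    mu_a = np.asarray(mu_a_stack, dtype=float)
    if mu_a.ndim != 3:
        raise ValueError("mu_a stack must be (n_wavelengths, nz, nx)")
    if np.any(mu_a < 0) or np.any(~np.isfinite(mu_a)):
        raise ValueError("mu_a must be finite and non-negative")
    mu_bar = mu_a.mean(axis=2)                       # (n_lam, nz), cm^-1
    mu_eff = model.effective_attenuation(mu_bar)     # cm^-1
    dz_cm = pitch_mm / 10.0
    # trapezoidal cumulative optical depth, zero at the first row
    mids = 0.5 * (mu_eff[:, 1:] + mu_eff[:, :-1]) * dz_cm
    tau = np.concatenate([np.zeros((mu_eff.shape[0], 1)),
                          np.cumsum(mids, axis=1)], axis=1)
    phi = np.exp(-tau)
    return np.repeat(phi[:, :, None], mu_a.shape[2], axis=2)


def initial_pressure(phantom: Phantom, mu_a_stack: np.ndarray,
                     fluence_stack: np.ndarray) -> np.ndarray:
    """p0(lambda, z, x) = Grueneisen * mu_a * Phi (arbitrary linear units)."""
    if mu_a_stack.shape != fluence_stack.shape:
        raise ValueError("mu_a and fluence stacks must have equal shapes")
    gamma = phantom.grueneisen
    if np.ndim(gamma) == 2 and np.shape(gamma) != phantom.grid.shape:
        raise ValueError("Grueneisen map shape mismatch")
    return np.asarray(gamma) * mu_a_stack * fluence_stack
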