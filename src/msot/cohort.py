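"""Synthetic patient cohorts for the benign-vs-malignant group comparison.

Each case is a thyroid-nodule scene with a true nodule oxygen saturation
drawn from its group's distribution; malignant nodules are shifted down by
the effect size ``delta_so2``. The default cohort mirrors the clinical data
set: 16 benign and 11 malignant nodules.

For statistical experiments (type-I error / power over hundreds of cohorts)
each case carries an ``observed_so2`` summary — the true per-nodule SO2 plus
Gaussian measurement noise — so the group test can be exercised without
rendering acoustics. Setting ``render=True`` additionally synthesises the
full multispectral sinogram for each case through the acoustic chain.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import Phantom, build_phantom
from .simulate import MultispectralSinogram, simulate_stack
from .spectra import ReferenceMatrix, WavelengthGrid

__all__ = ["CohortCase", "simulate_cohort", "DEFAULT_COHORT"]

#: Study conditions of the clinical cohort and the statistical examples.
DEFAULT_COHORT = {
    "n_benign": 16,
    "n_malignant": 11,
    "benign_so2_mean": 0.72,
    "so2_sd": 0.05,        # between-nodule spread of true SO2
    "noise_so2": 0.05,     # per-case measurement noise on the ROI mean
}


@dataclass
class CohortCase:
    label: str                     # "benign" | "malignant"
    seed: int
    true_so2: float
    observed_so2: float
    scene: dict = field(default_factory=dict)
    phantom: Phantom | None = None
    sinogram: MultispectralSinogram | None = None


def _case_scene(base_scene: dict, so2: float) -> dict:
    scene = {k: (dict(v) if isinstance(v, dict) else v)
             for k, v in base_scene.items()}
    nod = dict(scene.get("nodule", {"center_mm": (0.0, 20.0), "radius_mm": 3.0}))
    nod["so2"] = so2
    scene["nodule"] = nod
    return scene


def simulate_cohort(config: dict | None, n_benign: int, n_malignant: int,
                    delta_so2: float, seed: int, render: bool = False,
                    refs: ReferenceMatrix | None = None,
                    wavelengths: WavelengthGrid | None = None) -> list[CohortCase]:
    """Draw a labelled cohort of nodule cases; deterministic per master seed.

    ``delta_so2`` shifts the malignant group's mean true SO2 down relative to
    benign; 0 makes the two groups exchangeable.
    """
    if n_benign < 1 or n_malignant < 1:
        raise ValueError("need at least one case per group")
    if not -1.0 <= delta_so2 <= 1.0:
        raise ValueError("delta_so2 must be in [-1, 1]")
    cfg = dict(DEFAULT_COHORT)
    scene = {}
    if config:
        scene = dict(config.get("scene", {}))
        for k in cfg:
            if k in config:
                cfg[k] = config[k]
    ss = np.random.SeedSequence(seed)
    case_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                  ss.spawn(n_benign + n_malignant)]
    rng = np.random.default_rng(ss.spawn(1)[0])
    labels = ["benign"] * n_benign + ["malignant"] * n_malignant
    cases = []
    for label, cseed in zip(labels, case_seeds):
        mean = cfg["benign_so2_mean"] - (delta_so2 if label == "malignant" else 0.0)
        true_so2 = float(np.clip(rng.normal(mean, cfg["so2_sd"]), 0.0, 1.0))
        observed = float(np.clip(rng.normal(true_so2, cfg["noise_so2"]), 0.0, 1.0))
        case = CohortCase(label=label, seed=cseed, true_so2=true_so2,
                          observed_so2=observed,
                          scene=_case_scene(scene, true_so2))
        if render:
            if refs is None or wavelengths is None:
                raise ValueError("render=True requires refs and wavelengths")
            case.phantom = build_phantom(case.scene, seed=cseed)
            case.sinogram = simulate_stack(case.phantom, wavelengths, refs,
                                           seed=cseed)
        cases.append(case)
    return cases
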