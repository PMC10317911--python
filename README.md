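# msot

Simulation and analysis toolkit for **multispectral optoacoustic tomography
(MSOT)** of tissue cross-sections, built for studying how far hand-held
optoacoustic imaging can be pushed for thyroid-nodule characterisation —
and where its physics gets in the way.

MSOT detects ultrasound generated by pulsed-laser absorption and, by
scanning the illumination wavelength (here 680–1195 nm, 14 wavelengths),
maps the chromophores that absorb it: oxy- and deoxyhemoglobin, water,
lipid, collagen, melanin. The package implements the full processing chain
on synthetic phantoms with known ground truth:

1. **Phantoms & acquisition** — 2-D concentration maps (skin layer, vessels
   of known diameter, nodules with microvessel fields, reflective capsule
   interfaces), wavelength-dependent depth fluence Φ(λ, z), initial
   pressure p0 = Γ·μa·Φ, and sinogram synthesis for a 256-element, 125°
   concave array with a 3.4 MHz / 60% (−6 dB) band-limited impulse
   response, plus additive noise.
2. **Preprocessing** — 1195 nm discard, zero-phase Butterworth band-pass
   0.5–12 MHz, explicit pass-through denoise stage.
3. **Model-based reconstruction** — non-negative least squares with
   shearlet-L1 regularization,

       min_{x ≥ 0} ½‖Ax − y‖² + λ‖Sx‖₁,

   solved by SpaRSA (Barzilai–Borwein steps, monotone backtracking) with a
   support-restricted debiasing polish; L-curve selection of λ; delay-and-
   sum backprojection as baseline.
4. **Spectral unmixing** — per-pixel NNLS against literature spectra
   (linear) and regularized NMF, ½‖X − HWᵀ‖² + α‖H‖₁ + β‖W‖², with k = 8
   components (blind), plus cosine-similarity matching of blind components
   to chromophores.
5. **Analysis** — SO2 = HbO2/(HbO2+HbR) maps, ROI mean spectra, Michelson
   contrast resolution, FWHM vessel diametry with sub-pixel crossings,
   estimated-vs-true diameter regression, and Mann–Whitney group
   comparison of benign vs malignant nodule cohorts.

See `docs/methods.md` for models, defaults, and limitations.

## Worked example

The numbered scripts under `analysis/` run the studies end to end and
write their tables under `results/`. For instance:

```bash
python analysis/01_simulate_phantom.py
python analysis/02_reconstruct.py
python analysis/03_unmix_and_report.py
```

prints (numbers from an actual run, seed 1):

```
rel MSE: linear 4.74% | blind (k=8) 0.676%
blind component matching (cosine):
    component 0 -> melanin  score 0.934
    component 6 -> hbr      score 0.819
    component 2 -> hbo2     score 0.720
    ...
       roi  n_pixels  coef_hbo2  coef_hbr  ...  so2_mean       cr
    nodule       812   0.013497  0.001901  ...  0.795023 0.839265
```

Blind unmixing leaves an order of magnitude less unexplained image energy
than the literature-spectra fit (0.68% vs 4.7%) because it absorbs the
spectral colouring the fluence imposes; the nodule ROI's mean SO2 (0.795)
recovers the simulated 0.7–0.92 mixture of nodule tissue and microvessels.
The artefact studies (`05_artifact_studies.py`) show the mechanisms that
limit quantification:

```
colouring notch: recovered/ref HbO2 ratio minimal at 970 nm
rel MSE on coloured stack: linear 12.21% vs blind 0.00%
reflection ghost: source z=10 mm, interface z=15 mm -> ghost at z=20.0 mm
```

— a water-rich dermis depresses deep-vessel spectra exactly at the water
band, and a capsule-like interface mirrors a superficial source to the
geometrically reflected position at the interface's reflection coefficient.

As a library:

```python
from msot import run_pipeline
record = run_pipeline({"scene": {}, "geometry": {}, "master_seed": 1},
                      out_dir="out")
print(record["roi_table"])
```

A `msot` CLI with `simulate | preprocess | reconstruct | unmix | analyze |
pipeline` subcommands wraps the same functions.

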