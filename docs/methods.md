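# Methods

This note documents the models, numerical choices, and known limits of the
`msot` package: a simulation-and-analysis chain for multispectral
optoacoustic tomography (MSOT) of tissue cross-sections, built around the
processing pipeline used for hand-held clinical thyroid imaging —
model-based reconstruction with shearlet-L1 sparsity, linear and blind
spectral unmixing, and vessel/SO2/ROI analysis.

## Imaging model

A pulsed laser at wavelength λ deposits energy in tissue; the local initial
pressure is

    p0(r, λ) = Γ(r) · μa(r, λ) · Φ(r, λ),

with Γ the Grüneisen parameter (default 1 everywhere — the scanner's
wavelength-independent system constant absorbs the overall scale), μa the
optical absorption, and Φ the light fluence. Absorption is linear in the
relative chromophore concentrations,

    μa(r, λ) = Σ_k C_k(r) · μa_k(λ),

over six chromophores: HbO2, HbR, water, lipid, collagen, melanin.

**Literature spectra.** The packaged tables (`msot/data/*.csv`, 10 nm
spacing, 670–1200 nm) are compiled from standard published anchor values:
hemoglobin extinction converted to whole-blood μa at 150 g/L, pure-water
absorption with the 975 nm band, fat with the 930 nm CH band, collagen with
the broad rise beyond 1000 nm, and a λ^-3.48 power-law pigment model for
melanin. Units are cm⁻¹ per unit *relative* concentration (1 = whole blood /
pure water / pure fat / dense collagen / reference pigmentation); absolute
molarity is out of scope. Interpolation onto acquisition grids is piecewise
linear; extrapolation outside the table support is an error. The tables
reproduce the features the analyses rely on: the near-isosbestic point at
800 nm, the deoxyhemoglobin local maximum at 760 nm, and the water peak at
970 nm among the acquisition wavelengths at or below 1100 nm.

**Fluence.** Φ is a 1-D depth-only Beer–Lambert model: per wavelength, the
laterally averaged absorption of each image row feeds a diffusion-style
effective attenuation μ_eff = sqrt(3 μa (μa + μs')) with constant reduced
scattering μs' = 10 cm⁻¹, integrated over depth (trapezoid) and normalised
to 1 at the top row. This is intentionally the *simplest* model that
produces spectral colouring — wavelengths absorbed strongly by superficial
water lose fluence faster with depth — because the study of that artefact,
not radiative transport accuracy, is the point. No diffusion/RTE solver, no
lateral structure, no refractive effects. The reconstruction chain
deliberately does not correct fluence; the colouring notch experiments
measure the consequence.

**Reflections.** Acoustic-impedance interfaces are straight segments with a
reflection coefficient r ∈ [0, 1]. The model is specular, single-bounce and
one-sided, applied in *source space*: every source pixel on the probe side
of an interface deposits an r-scaled copy at its mirror position. This
matches how an inversion that models only direct propagation mislocalises a
reflected wave, which is exactly the ghost-artefact mechanism being
emulated; no wave-equation reflection is computed.

## Acquisition model

The detector is a concave arc: 256 elements (desk-scale experiments often
use 48–128), 125° coverage, 40 mm radius, centre of curvature 20 mm below
the probe face on the symmetry axis. Sampling is 40 MS/s with the time
window fitted to the image grid; the speed of sound is a single effective
1.5 mm/µs (an optional couplant/tissue pair shifts time-of-flight offsets
only — refraction is not modelled, keeping the operator linear).

The discrete forward operator factorises as A = H · D · M:

* **M (ring sum):** each pixel contributes its value, weighted by
  pitch²/d, to the two time samples bracketing its flight time d/c to each
  element (linear interpolation). This is the standard interpolated-matrix
  discretisation of the 2-D circular-integral forward model.
* **D:** central-difference time derivative (the N-shaped optoacoustic
  signature).
* **H:** convolution with the transducer impulse response — a zero-mean
  Gaussian-windowed 3.4 MHz tone whose −6 dB band edges sit at fc(1 ± 0.3)
  (60% fractional bandwidth), normalised to unit in-band peak gain.

`forward_project` evaluates this model matrix-free; `SystemMatrix` stores M
sparse and applies D and H separably with exact adjoints (the adjoint test
holds to ~1e−15). Simulation and reconstruction share this one
discretisation — a deliberate inverse crime: the acceptance experiments
probe the solver/regularisation/unmixing chain, not operator mismatch, and
this is stated rather than hidden.

## Preprocessing

1195 nm acquisitions are dropped (the probe couplant absorbs strongly
there), every trace is band-passed 0.5–12 MHz with a zero-phase
(forward–backward) order-4 Butterworth — zero phase so arrival times, hence
geometry, are untouched; whether the original pipeline was zero-phase is
unstated, so this choice is documented here — and the denoising stage is an
explicit pass-through: the learned denoiser used on clinical data is out of
scope and is not approximated.

## Reconstruction

Per wavelength the solver addresses

    min_{x ≥ 0}  ½‖A x − y‖² + λ ‖S x‖₁

with S a sparsifying transform. Solver: SpaRSA (sparse reconstruction by
separable approximation) with Barzilai–Borwein step initialisation,
monotone backtracking acceptance (recorded objectives are non-increasing),
and stopping at relative objective change < 1e−6 or 200 iterations.
Because S is a redundant Parseval frame the exact proximal map of ‖S·‖₁ is
not separable; the implementation thresholds in the coefficient domain,
synthesises, then projects onto the non-negative orthant — a documented
approximation standard for frame-based penalties.

**Debiasing.** The band-limited operator is ill-conditioned, and
first-order iterations alone recover sharp supports but biased amplitudes.
As is customary for this solver family, an optional (default-on) debiasing
phase re-solves the data term restricted to the positive support with
projected LSQR passes (prune negatives, re-solve; 400 inner iterations, 2
passes by default). With λ → 0 on noiseless data this reaches the dense
NNLS solution to ~1e−6 relative error. A corollary worth knowing: the
finite iteration budget acts as implicit early-stopping regularisation, so
on the scenes tested the ground-truth RMSE is monotone non-decreasing in λ
— small λ never "overfits" the way a fully converged variational solution
would. The L-curve (maximum curvature of log residual vs log L1 penalty,
computed without debiasing so the curve reflects the penalized solutions)
therefore guards against over-smoothing rather than against overfitting.

**Transform.** The default S is an in-repo cone-adapted directional
Parseval frame: log-radial octave bands (3 scales) split into orientation
wedges whose count doubles per scale, built as smooth frequency-domain
windows, explicitly symmetrised under ξ → −ξ (the aliased Nyquist line is
orientation-ambiguous) and normalised so Σ|Ψ_i|² = 1 exactly — giving exact
tight-frame synthesis and Parseval energy. A separable orthonormal wavelet
(db4, PyWavelets) is available behind `transform="wavelet"`.

**Defaults.** Reconstruction pitch 0.1 mm (test grids smaller for speed);
λ defaults to `lambda_rel = 1e−3` × max|Aᵀy| over the stack — with
debiasing the recovered amplitudes are insensitive to λ across decades, and
the L-curve selector is available where a data-driven choice is wanted. One
A and one λ serve all wavelengths, preserving cross-wavelength scale. A
delay-and-sum backprojection is included only as a comparison baseline.

## Spectral unmixing

Operates on the 13 used wavelengths. **Linear:** per-pixel NNLS against the
literature-spectra matrix (scipy's active-set NNLS per pixel).
**Blind:** NMF of the pixels×wavelengths matrix,

    min_{H,W ≥ 0} ½‖X − H Wᵀ‖² + α‖H‖₁ + β‖W‖²_F,

k = 8 components, L1 on the pixel coefficients (sparse contribution of
absorbers), L2 on the spectra (suppresses high-frequency noise), solved by
multiplicative updates from an NNDSVD initialisation with seed-controlled
fill-in of zero entries; deterministic per seed, objective non-increasing.
The residual metric is rel-MSE = 100·‖X − X̂‖²/‖X‖², the share of stack
energy the fit leaves unexplained. Blind components are linked to
chromophores greedily by descending cosine similarity, each chromophore and
component used at most once.

## Analysis

* **SO2** = HbO2/(HbO2+HbR) per pixel, masked below a total-hemoglobin
  threshold (default 1e−6 in coefficient units).
* **ROI spectra**: arithmetic means over boolean masks taken from simulator
  ground truth or explicit config (stand-in for manual ultrasound
  segmentation).
* **Contrast resolution**: Michelson-style (μ_roi − μ_bg)/(μ_roi + μ_bg),
  bounded in [−1, 1] on non-negative images. The clinical pipeline's exact
  CR formula is defined in a supplement not available here; this stand-in
  is consistent with reported values ≈ 1 for near-zero backgrounds but is
  not verified against it.
* **FWHM diametry**: bilinear profile sampling (step ≤ pitch), half-max at
  (peak + baseline)/2 with the baseline the smaller profile end value,
  sub-pixel crossings by linear interpolation.
* **Diameter regression**: OLS of estimated on true, R² = 1 − SSres/SStot.
* **Group comparison**: two-sided Mann–Whitney U at α = 0.05 (distribution-
  free, appropriate at n = 16/11); Welch's t behind a flag. No
  multiple-testing correction across the HbO2/HbR/SO2 tests by default
  (matching how such panels are usually reported); a Bonferroni adjustment
  is the caller's one-liner.

## Synthetic cohorts

`simulate_cohort` draws per-case true nodule SO2 from N(0.72, 0.05²)
(benign), shifting the malignant mean down by the effect size Δso2, with
cohort sizes defaulting to 16 benign / 11 malignant. Each case carries an
`observed_so2` = truth + N(0, 0.05²) measurement noise, clipped to [0, 1],
so test calibration over hundreds of cohorts runs at the statistics level;
`render=True` additionally synthesises each case's full sinogram. The
benign mean and spreads are field-realistic choices fixed once; they are
*not* fitted to any measured cohort. What the Monte-Carlo results show is
therefore the calibration and power of the test under these idealised
conditions — real nodule SO2 estimates carry reconstruction, colouring and
segmentation errors that this summary-level noise does not model.

## Problem sizes and runtimes

Experiments are sized for a single CPU: resolution sweep 64×64 at 0.1 mm
(256 elements, 40 dB SNR), point-target study 65×65 at 0.05 mm (noiseless,
L-curve λ), colouring study 165×40 at 0.1 mm × 13 wavelengths (128
elements), cohort calibration 200 cohorts per condition. The full test
suite runs in ~5 minutes; the acceptance script in ~3.

## What the synthetic data does and does not show

The phantoms reproduce the *mechanisms* of the clinical artefacts —
mirrored ghosts, the 970–1000 nm colouring notch, hemoglobin/lipid spectral
cross-talk, collagen masked by stronger absorbers — under a 2-D, single
effective-sound-speed, depth-only-fluence, inverse-crime setup. Passing
tests certify the pipeline's internal correctness and that these mechanisms
behave as described; they do not certify quantitative accuracy on real
tissue, where 3-D acoustics, sound-speed heterogeneity, lateral fluence
structure, motion, and model mismatch all enter. Measured per-patient
quantities (diameter pairs beyond the four fully tabulated ones, in vivo
residuals, CR values) are not reproduction targets.

## Known limitations

2-D in-plane model only (no elevation sensitivity); no acoustic attenuation
or dispersion; one-bounce reflections; NNDSVD+multiplicative NMF finds a
local optimum (seeded, deterministic, but initialisation-dependent); the
frame-prox approximation means the L1 subproblem is inexact; debiasing on
very noisy data can overfit the support and is best disabled there.
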