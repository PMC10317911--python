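"""Downstream analysis: SO2 maps, ROI spectra, contrast, diametry, statistics.

Implements the quantities the clinical analysis reports per case — pixelwise
oxygen saturation from the hemoglobin coefficient maps, mean ROI spectra,
Michelson-style contrast resolution, full-width-at-half-maximum vessel
diametry along profile lines with sub-pixel crossings — plus the cohort
statistics: the MSOT-vs-truth diameter regression (OLS R^2) and the
benign-vs-malignant group comparison (two-sided Mann–Whitney U by default,
Welch's t behind a flag).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import map_coordinates

from .phantom import ImageGrid
from .reconstruct import MultispectralImage

__all__ = ["ProfileLine", "DiameterMeasurement", "RoiStats", "GroupComparison",
           "so2_map", "roi_mean_spectrum", "contrast_resolution",
           "fwhm_diameter", "diameter_regression", "compare_groups",
           "case_report"]


@dataclass(frozen=True)
class ProfileLine:
    """Straight sampling line in mm coordinates with step <= pixel pitch."""

    p0_mm: tuple
    p1_mm: tuple
    step_mm: float

    def __post_init__(self):
        if np.allclose(self.p0_mm, self.p1_mm):
            raise ValueError("profile endpoints must be distinct")
        if self.step_mm <= 0:
            raise ValueError("step must be positive")

    def sample_points(self) -> np.ndarray:
        p0 = np.asarray(self.p0_mm, float)
        p1 = np.asarray(self.p1_mm, float)
        length = float(np.linalg.norm(p1 - p0))
        n = int(np.floor(length / self.step_mm)) + 1
        t = np.linspace(0.0, 1.0, n)
        return p0[None, :] + t[:, None] * (p1 - p0)[None, :]


@dataclass
class DiameterMeasurement:
    fwhm_mm: float
    profile: np.ndarray
    positions_mm: np.ndarray
    half_max: float
    crossings_mm: tuple


@dataclass
class RoiStats:
    mean_spectrum: np.ndarray | None = None
    coefficients: dict = field(default_factory=dict)
    so2_mean: float | None = None
    cr: float | None = None


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    alpha: float
    reject: bool
    group_values: dict = field(default_factory=dict)


def so2_map(c_hbo2: np.ndarray, c_hbr: np.ndarray,
            min_total: float = 1e-6) -> np.ma.MaskedArray:
    """SO2 = HbO2 / (HbO2 + HbR), masked where total blood < ``min_total``."""
    c_hbo2 = np.asarray(c_hbo2, float)
    c_hbr = np.asarray(c_hbr, float)
    if c_hbo2.shape != c_hbr.shape:
        raise ValueError("coefficient maps must have equal shapes")
    if np.any(c_hbo2 < 0) or np.any(c_hbr < 0):
        raise ValueError("coefficient maps must be non-negative")
    total = c_hbo2 + c_hbr
    mask = total < min_total
    with np.errstate(invalid="ignore", divide="ignore"):
        so2 = np.where(mask, 0.0, c_hbo2 / np.where(mask, 1.0, total))
    return np.ma.MaskedArray(so2, mask=mask)


def roi_mean_spectrum(images: MultispectralImage, mask: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the pixel spectra over a boolean ROI mask."""
    mask = np.asarray(mask, bool)
    if mask.shape != images.image_grid.shape:
        raise ValueError("mask shape does not match the image grid")
    if not mask.any():
        raise ValueError("empty ROI mask")
    return images.data[:, mask].mean(axis=1)


def contrast_resolution(image: np.ndarray, roi_mask: np.ndarray,
                        background_mask: np.ndarray) -> float:
    """Michelson-style contrast: (mu_roi - mu_bg) / (mu_roi + mu_bg)."""
    roi_mask = np.asarray(roi_mask, bool)
    background_mask = np.asarray(background_mask, bool)
    if not roi_mask.any() or not background_mask.any():
        raise ValueError("ROI and background masks must be non-empty")
    if np.any(roi_mask & background_mask):
        raise ValueError("ROI and background masks must be disjoint")
    mu_roi = float(np.mean(image[roi_mask]))
    mu_bg = float(np.mean(image[background_mask]))
    if mu_roi + mu_bg == 0:
        raise ValueError("contrast undefined: both region means are zero")
    return (mu_roi - mu_bg) / (mu_roi + mu_bg)


def sample_profile(image: np.ndarray, grid: ImageGrid,
                   line: ProfileLine) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear samples of ``image`` along the line; returns (distance_mm, values)."""
    if line.step_mm > grid.pitch_mm + 1e-12:
        raise ValueError("profile step must not exceed the pixel pitch")
    pts = line.sample_points()
    cols = (pts[:, 0] - grid.origin_mm[0]) / grid.pitch_mm
    rows = (pts[:, 1] - grid.origin_mm[1]) / grid.pitch_mm
    vals = map_coordinates(np.asarray(image, float), [rows, cols],
                           order=1, mode="nearest")
    dist = np.linalg.norm(pts - pts[0], axis=1)
    return dist, vals


def fwhm_diameter(image: np.ndarray, grid: ImageGrid,
                  line: ProfileLine) -> DiameterMeasurement:
    """FWHM of the dominant peak along a profile line, in mm.

    The half-maximum level is (peak + baseline)/2 with the baseline taken as
    the smaller of the two profile end values; crossings are located by
    linear interpolation between samples (sub-pixel).
    """
    dist, vals = sample_profile(image, grid, line)
    peak_idx = int(np.argmax(vals))
    peak = float(vals[peak_idx])
    baseline = float(min(vals[0], vals[-1]))
    if peak <= baseline or np.allclose(vals, vals[0]):
        raise ValueError("flat profile: no peak above the baseline")
    half = 0.5 * (peak + baseline)

    def _cross(indices):
        """Walk outward from the peak; interpolate the first sub-half crossing."""
        prev = peak_idx
        for i in indices:
            if vals[i] < half:
                f = (vals[prev] - half) / (vals[prev] - vals[i])
                return float(dist[prev] + f * (dist[i] - dist[prev]))
            prev = i
        return None

    left = _cross(range(peak_idx - 1, -1, -1))
    right = _cross(range(peak_idx + 1, len(vals)))
    if left is None or right is None:
        raise ValueError("no half-maximum crossing on one side of the peak")
    return DiameterMeasurement(fwhm_mm=float(right - left), profile=vals,
                               positions_mm=dist, half_max=half,
                               crossings_mm=(float(left), float(right)))


def diameter_regression(pairs) -> dict:
    """OLS of estimated on true diameter; R^2 = 1 - SS_res / SS_tot.

    ``pairs`` is a sequence of (estimated_mm, true_mm).
    """
    pairs = np.asarray(list(pairs), float)
    if pairs.ndim != 2 or pairs.shape[0] < 2 or pairs.shape[1] != 2:
        raise ValueError("need at least two (estimated, true) pairs")
    est, true = pairs[:, 0], pairs[:, 1]
    if np.allclose(true, true[0]):
        raise ValueError("true diameters are constant; regression undefined")
    fit = stats.linregress(true, est)
    pred = fit.intercept + fit.slope * true
    ss_res = float(np.sum((est - pred) ** 2))
    ss_tot = float(np.sum((est - est.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return {"r2": r2, "slope": float(fit.slope),
            "intercept": float(fit.intercept), "n": int(len(est))}


def compare_groups(benign, malignant, alpha: float = 0.05,
                   test: str = "mannwhitney") -> GroupComparison:
    """Two-sided comparison of per-nodule means between the two groups."""
    benign = np.asarray(list(benign), float)
    malignant = np.asarray(list(malignant), float)
    if benign.size < 3 or malignant.size < 3:
        raise ValueError("each group needs at least 3 cases")
    if test == "mannwhitney":
        res = stats.mannwhitneyu(benign, malignant, alternative="two-sided")
    elif test == "welch":
        res = stats.ttest_ind(benign, malignant, equal_var=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    p = float(res.pvalue)
    return GroupComparison(test=test, statistic=float(res.statistic),
                           p_value=p, alpha=alpha, reject=bool(p < alpha),
                           group_values={"benign": benign.tolist(),
                                         "malignant": malignant.tolist()})


def case_report(images: MultispectralImage, unmix_result, rois: dict,
                out_dir, provenance: dict | None = None,
                export_maps: bool = True) -> pd.DataFrame:
    """Per-ROI summary table (CSV) plus TIFF exports of coefficient/SO2 maps.

    ``rois`` maps ROI names to boolean masks. Fully determined by its inputs;
    rerunning writes byte-identical CSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = unmix_result.component_names or tuple(
        f"component_{i}" for i in range(unmix_result.coefficient_maps.shape[0]))
    rows = []
    maps = {n: unmix_result.coefficient_maps[i] for i, n in enumerate(names)}
    so2 = None
    if "hbo2" in maps and "hbr" in maps:
        so2 = so2_map(maps["hbo2"], maps["hbr"])
    bg_mask = None
    if "background" in rois:
        bg_mask = np.asarray(rois["background"], bool)
    for roi_name, mask in rois.items():
        mask = np.asarray(mask, bool)
        spectrum = roi_mean_spectrum(images, mask)
        row = {"roi": roi_name, "n_pixels": int(mask.sum())}
        for i, lam in enumerate(images.grid.wavelengths):
            row[f"mean_{lam:g}nm"] = spectrum[i]
        for n in names:
            row[f"coef_{n}"] = float(maps[n][mask].mean())
        if so2 is not None:
            valid = mask & ~so2.mask
            row["so2_mean"] = float(so2.data[valid].mean()) if valid.any() else np.nan
        if bg_mask is not None and roi_name != "background" and \
                not np.any(mask & bg_mask):
            total = images.data.sum(axis=0)
            row["cr"] = contrast_resolution(total, mask, bg_mask)
        rows.append(row)
    table = pd.DataFrame(rows)
    prov = dict(provenance or {})
    prov.update({"mode": unmix_result.mode, "seed": unmix_result.seed,
                 "alpha_l1": unmix_result.alpha_l1,
                 "beta_l2": unmix_result.beta_l2})
    with open(out / "roi_report.csv", "w") as fh:
        for k in sorted(prov):
            fh.write(f"# {k}={prov[k]}\n")
        table.to_csv(fh, index=False, float_format="%.8g")
    if export_maps:
        import tifffile
        for n in names:
            tifffile.imwrite(out / f"coef_{n}.tif",
                             maps[n].astype(np.float32))
        if so2 is not None:
            tifffile.imwrite(out / "so2.tif",
                             so2.filled(np.nan).astype(np.float32))
    return table
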