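"""Literature optical-absorption spectra of tissue chromophores.

Houses compiled near-infrared absorption tables for the six chromophores the
thyroid analysis unmixes against (oxy-/deoxyhemoglobin, water, lipid,
collagen, melanin), aligned to the acquisition wavelength grid, plus the
interpolation and spectrum-matching utilities the rest of the pipeline uses.

Spectra are expressed in cm^-1 per unit *relative* concentration: a
concentration map value of 1.0 means whole blood (for Hb species), pure
water/fat, dense collagen, or reference epidermal pigmentation. Absolute
molarity is deliberately out of scope; the system constant of the scanner is
wavelength-independent and absorbs the overall scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "DEFAULT_WAVELENGTHS_NM",
    "CHROMOPHORES",
    "WavelengthGrid",
    "AbsorptionSpectrum",
    "ReferenceMatrix",
    "load_table",
    "load_reference_spectra",
    "interpolate_spectrum",
    "cosine_similarity",
]

#: The 14 acquisition wavelengths of the hand-held scanner (nm).
DEFAULT_WAVELENGTHS_NM = (
    680, 700, 730, 760, 800, 850, 900, 930, 970, 1000, 1030, 1064, 1100, 1195
)

#: Chromophores with packaged literature tables.
CHROMOPHORES = ("hbo2", "hbr", "h2o", "lipid", "collagen", "melanin")

_ALIASES = {
    "hbo2": "hbo2", "oxy": "hbo2", "oxyhemoglobin": "hbo2",
    "hbr": "hbr", "hb": "hbr", "deoxy": "hbr", "deoxyhemoglobin": "hbr",
    "h2o": "h2o", "water": "h2o",
    "lipid": "lipid", "fat": "lipid",
    "collagen": "collagen",
    "melanin": "melanin",
}


def canonical_name(name: str) -> str:
    key = name.strip().lower()
    if key not in _ALIASES:
        raise KeyError(
            f"unknown chromophore {name!r}; supported: {sorted(set(_ALIASES.values()))}"
        )
    return _ALIASES[key]


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing acquisition wavelengths in nm, within 680-1195."""

    wavelengths: tuple = DEFAULT_WAVELENGTHS_NM

    def __post_init__(self):
        lam = np.asarray(self.wavelengths, dtype=float)
        if lam.ndim != 1 or lam.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D sequence")
        if not np.all(np.diff(lam) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if lam[0] < 680 or lam[-1] > 1195:
            raise ValueError("wavelengths must lie within [680, 1195] nm")
        object.__setattr__(self, "wavelengths", tuple(float(v) for v in lam))

    def __len__(self):
        return len(self.wavelengths)

    def __iter__(self):
        return iter(self.wavelengths)

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.wavelengths, dtype=float)

    def drop(self, drop_nm) -> "WavelengthGrid":
        drop = {float(v) for v in np.atleast_1d(drop_nm)}
        missing = drop - set(self.wavelengths)
        if missing:
            raise ValueError(f"wavelengths not in grid: {sorted(missing)}")
        kept = tuple(w for w in self.wavelengths if w not in drop)
        return WavelengthGrid(kept)

    def index_of(self, lam_nm: float) -> int:
        try:
            return self.wavelengths.index(float(lam_nm))
        except ValueError:
            raise ValueError(f"{lam_nm} nm is not on the grid") from None


@dataclass(frozen=True)
class AbsorptionSpectrum:
    """mu_a (cm^-1 per unit relative concentration) on a wavelength grid."""

    chromophore: str
    grid: WavelengthGrid
    mu_a: np.ndarray = field(repr=False)

    def __post_init__(self):
        mu = np.asarray(self.mu_a, dtype=float)
        if mu.shape != (len(self.grid),):
            raise ValueError("mu_a length must equal grid length")
        if not np.all(np.isfinite(mu)) or np.any(mu < 0):
            raise ValueError("mu_a values must be finite and non-negative")
        object.__setattr__(self, "mu_a", mu)


@dataclass(frozen=True)
class ReferenceMatrix:
    """Design matrix for linear unmixing: n_wavelengths x n_chromophores."""

    grid: WavelengthGrid
    chromophores: tuple
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.grid), len(self.chromophores)):
            raise ValueError("matrix shape must be (n_wavelengths, n_chromophores)")
        if np.any(~np.isfinite(m)) or np.any(m < 0):
            raise ValueError("reference matrix must be finite and non-negative")
        if np.any(m.max(axis=0) <= 0):
            raise ValueError("reference matrix has an all-zero column")
        object.__setattr__(self, "matrix", m)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.chromophores.index(canonical_name(name))]


def load_table(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Load a packaged literature table -> (wavelengths_nm, mu_a_cm1)."""
    name = canonical_name(name)
    path = resources.files("msot.data").joinpath(f"{name}.csv")
    with path.open("r") as fh:
        header = fh.readline().strip().split(",")
        if header != ["wavelength_nm", "mu_a_cm1"]:
            raise ValueError(f"bad table header in {name}.csv: {header}")
        rows = np.loadtxt(fh, delimiter=",")
    return rows[:, 0], rows[:, 1]


def interpolate_table(name: str, grid: WavelengthGrid) -> np.ndarray:
    lam, mu = load_table(name)
    target = grid.values
    if target[0] < lam[0] or target[-1] > lam[-1]:
        raise ValueError(
            f"requested wavelengths outside packaged table support "
            f"[{lam[0]}, {lam[-1]}] nm for {name!r}"
        )
    return np.interp(target, lam, mu)


def load_reference_spectra(names, grid: WavelengthGrid | None = None) -> ReferenceMatrix:
    """Assemble the literature-spectra design matrix on ``grid``.

    Piecewise-linear interpolation from the packaged tables; deterministic
    and reproducible offline (the tables ship with the package).
    """
    if grid is None:
        grid = WavelengthGrid()
    names = [canonical_name(n) for n in names]
    if not names:
        raise ValueError("names must be non-empty")
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromophore names")
    cols = [interpolate_table(n, grid) for n in names]
    return ReferenceMatrix(grid=grid, chromophores=tuple(names),
                           matrix=np.column_stack(cols))


def load_spectrum(name: str, grid: WavelengthGrid | None = None) -> AbsorptionSpectrum:
    if grid is None:
        grid = WavelengthGrid()
    return AbsorptionSpectrum(canonical_name(name), grid, interpolate_table(name, grid))


def interpolate_spectrum(spectrum: AbsorptionSpectrum, grid: WavelengthGrid) -> np.ndarray:
    """Piecewise-linear resampling of a spectrum onto a new grid (no extrapolation)."""
    src = spectrum.grid.values
    target = grid.values
    if target[0] < src[0] or target[-1] > src[-1]:
        raise ValueError("target grid extends outside the source spectrum support")
    return np.interp(target, src, spectrum.mu_a)


def cosine_similarity(a, b) -> float:
    """Scale-invariant cosine similarity between two spectra, in [-1, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("spectra must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero-norm input")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))
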