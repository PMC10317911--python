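"""Digital tissue phantoms for the simulated neck cross-section.

A phantom is a set of per-chromophore relative-concentration maps on a 2-D
image grid (x lateral, z depth in mm), plus the ground truth needed by the
downstream parameter-recovery analyses: vessel positions/diameters/SO2, the
nodule and skin masks, and any reflective interfaces (capsule, fascia).

Scenes emulate the anatomy the clinical scans show: a melanin/water-rich skin
layer, single vessels of known diameter, nodules with microvessel fields, and
straight acoustically reflective interfaces that mirror superficial sources
into deeper tissue.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import ReferenceMatrix, WavelengthGrid, canonical_name

__all__ = ["ImageGrid", "Phantom", "build_phantom", "compute_mu_a",
           "add_reflections"]


@dataclass(frozen=True)
class ImageGrid:
    """Pixel lattice: ``shape=(nz, nx)``, square pixels, mm coordinates.

    ``origin_mm`` is the (x, z) position of the *centre* of pixel (0, 0);
    row index increases with depth z, column index with lateral x.
    """

    shape: tuple
    pitch_mm: float
    origin_mm: tuple = (0.0, 0.0)

    def __post_init__(self):
        nz, nx = self.shape
        if nz < 1 or nx < 1 or self.pitch_mm <= 0:
            raise ValueError("invalid image grid")

    @property
    def nz(self) -> int:
        return self.shape[0]

    @property
    def nx(self) -> int:
        return self.shape[1]

    @property
    def x_mm(self) -> np.ndarray:
        return self.origin_mm[0] + np.arange(self.nx) * self.pitch_mm

    @property
    def z_mm(self) -> np.ndarray:
        return self.origin_mm[1] + np.arange(self.nz) * self.pitch_mm

    def mesh(self):
        return np.meshgrid(self.x_mm, self.z_mm)

    def pixel_centers(self) -> np.ndarray:
        """(nz*nx, 2) array of (x, z) pixel centres, row-major."""
        xx, zz = self.mesh()
        return np.column_stack([xx.ravel(), zz.ravel()])

    @classmethod
    def centered(cls, shape, pitch_mm, center_mm) -> "ImageGrid":
        nz, nx = shape
        x0 = center_mm[0] - (nx - 1) / 2 * pitch_mm
        z0 = center_mm[1] - (nz - 1) / 2 * pitch_mm
        return cls(shape=(nz, nx), pitch_mm=pitch_mm, origin_mm=(x0, z0))


@dataclass
class Phantom:
    """Concentration maps + ground truth for one simulated cross-section."""

    grid: ImageGrid
    concentration_maps: dict          # chromophore -> (nz, nx) map, >= 0
    grueneisen: float | np.ndarray = 1.0
    interfaces: list = field(default_factory=list)  # {"p0","p1","r"}
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, c in self.concentration_maps.items():
            c = np.asarray(c, dtype=float)
            if c.shape != self.grid.shape:
                raise ValueError(f"map {name!r} shape mismatch")
            if np.any(c < 0) or np.any(~np.isfinite(c)):
                raise ValueError(f"map {name!r} must be finite and non-negative")
            self.concentration_maps[name] = c
        for itf in self.interfaces:
            if not (0.0 <= itf["r"] <= 1.0):
                raise ValueError("reflection coefficient must be in [0, 1]")


def _disc_mask(grid: ImageGrid, center_mm, diameter_mm) -> np.ndarray:
    xx, zz = grid.mesh()
    r = diameter_mm / 2.0
    return (xx - center_mm[0]) ** 2 + (zz - center_mm[1]) ** 2 <= r * r + 1e-12


def _place_vessel(maps, grid, center_mm, diameter_mm, so2, blood=1.0):
    if diameter_mm < 2 * grid.pitch_mm:
        raise ValueError(
            f"vessel diameter {diameter_mm} mm below 2 x pitch "
            f"({2 * grid.pitch_mm} mm)")
    x, z = center_mm
    r = diameter_mm / 2
    if not (grid.x_mm[0] - 1e-9 <= x - r and x + r <= grid.x_mm[-1] + 1e-9
            and grid.z_mm[0] - 1e-9 <= z - r and z + r <= grid.z_mm[-1] + 1e-9):
        raise ValueError(f"vessel at {center_mm} mm extends outside the grid")
    if not 0.0 <= so2 <= 1.0:
        raise ValueError("vessel SO2 must be in [0, 1]")
    mask = _disc_mask(grid, center_mm, diameter_mm)
    maps["hbo2"][mask] = blood * so2
    maps["hbr"][mask] = blood * (1.0 - so2)
    return mask


def build_phantom(config: dict, seed: int = 0) -> Phantom:
    """Build a phantom from a scene description; deterministic per (config, seed).

    Config keys (all optional except geometry):
      shape, pitch_mm, origin_mm          - image grid
      background: {chromophore: value}    - uniform background concentrations
      skin: {thickness_mm, melanin, h2o}  - superficial layer
      vessels: [{center_mm, diameter_mm, so2, blood}]
      nodule: {center_mm, radius_mm, so2, blood,
               microvessels: {count, diameter_mm, so2, blood}}
      interfaces: [{p0_mm, p1_mm, r}]     - straight reflective segments
      grueneisen                          - scalar Grueneisen parameter
    """
    grid = ImageGrid(shape=tuple(config["shape"]),
                     pitch_mm=float(config["pitch_mm"]),
                     origin_mm=tuple(config.get("origin_mm", (0.0, 0.0))))
    rng = np.random.default_rng(seed)
    maps = {canonical_name(k): np.full(grid.shape, float(v))
            for k, v in config.get("background", {}).items()}
    for key in ("hbo2", "hbr"):
        maps.setdefault(key, np.zeros(grid.shape))
    gt: dict = {"vessels": [], "masks": {}, "so2": {}}

    skin = config.get("skin")
    if skin is not None:
        depth = float(skin.get("thickness_mm", 1.0))
        mask = grid.mesh()[1] - grid.z_mm[0] < depth
        for chrom in ("melanin", "h2o", "collagen"):
            if chrom in skin:
                maps.setdefault(chrom, np.zeros(grid.shape))
                maps[chrom][mask] = float(skin[chrom])
        gt["masks"]["skin"] = mask

    for v in config.get("vessels", []):
        mask = _place_vessel(maps, grid, tuple(v["center_mm"]),
                             float(v["diameter_mm"]), float(v.get("so2", 0.9)),
                             float(v.get("blood", 1.0)))
        gt["vessels"].append({"center_mm": tuple(v["center_mm"]),
                              "diameter_mm": float(v["diameter_mm"]),
                              "so2": float(v.get("so2", 0.9)),
                              "mask": mask})

    nod = config.get("nodule")
    if nod is not None:
        center = tuple(nod["center_mm"])
        radius = float(nod["radius_mm"])
        nmask = _disc_mask(grid, center, 2 * radius)
        nod_so2 = float(nod.get("so2", 0.7))
        base_blood = float(nod.get("blood", 0.05))
        maps["hbo2"][nmask] = base_blood * nod_so2
        maps["hbr"][nmask] = base_blood * (1.0 - nod_so2)
        gt["masks"]["nodule"] = nmask
        gt["so2"]["nodule"] = nod_so2
        mv = nod.get("microvessels")
        if mv is not None:
            count = int(mv["count"])
            d_mm = float(mv.get("diameter_mm", 0.25))
            mv_so2 = float(mv.get("so2", nod_so2))
            mv_blood = float(mv.get("blood", 1.0))
            placed = 0
            attempts = 0
            while placed < count:
                attempts += 1
                if attempts > 1000 * count:
                    raise ValueError("could not place requested microvessels")
                ang = rng.uniform(0, 2 * np.pi)
                rad = (radius - d_mm) * np.sqrt(rng.uniform())
                c = (center[0] + rad * np.cos(ang), center[1] + rad * np.sin(ang))
                try:
                    mask = _place_vessel(maps, grid, c, d_mm, mv_so2, mv_blood)
                except ValueError:
                    continue
                gt["vessels"].append({"center_mm": c, "diameter_mm": d_mm,
                                      "so2": mv_so2, "mask": mask})
                placed += 1

    interfaces = [{"p0": tuple(i["p0_mm"]), "p1": tuple(i["p1_mm"]),
                   "r": float(i["r"])} for i in config.get("interfaces", [])]
    return Phantom(grid=grid, concentration_maps=maps,
                   grueneisen=float(config.get("grueneisen", 1.0)),
                   interfaces=interfaces, ground_truth=gt)


def compute_mu_a(phantom: Phantom, grid: WavelengthGrid,
                 refs: ReferenceMatrix) -> np.ndarray:
    """Absorption stack mu_a(lambda, z, x) = sum_k C_k(z, x) * mu_a_k(lambda), cm^-1."""
    if refs.grid.wavelengths != grid.wavelengths:
        raise ValueError("reference matrix grid does not match requested grid")
    missing = [k for k in phantom.concentration_maps if k not in refs.chromophores]
    if missing:
        raise ValueError(f"no reference spectrum for chromophore(s) {missing}")
    nz, nx = phantom.grid.shape
    stack = np.zeros((len(grid), nz, nx))
    for name, c in phantom.concentration_maps.items():
        stack += refs.column(name)[:, None, None] * c[None, :, :]
    return stack


def add_reflections(p0: np.ndarray, phantom: Phantom) -> np.ndarray:
    """Add mirrored ghost sources across each reflective interface.

    For every source pixel on the probe side of an interface segment, a copy
    scaled by the reflection coefficient r is deposited at the geometrically
    mirrored position (nearest pixel); sources on the far side are left
    untouched (single-bounce, one-sided specular model). This reproduces the
    artefact mechanism by which an inversion model that only accounts for
    direct propagation localises the reflected wave at the mirror point.
    """
    grid = phantom.grid
    if p0.shape != grid.shape:
        raise ValueError("p0 shape mismatch")
    out = p0.astype(float).copy()
    if not phantom.interfaces:
        return out
    centers = grid.pixel_centers()          # (N, 2) (x, z)
    vals = p0.ravel()
    nz, nx = grid.shape
    # the probe sits above the tissue: reference point well before the surface
    probe_ref = np.array([0.0, grid.z_mm[0] - 1e3])
    for itf in phantom.interfaces:
        r = float(itf["r"])
        if not (0.0 <= r <= 1.0):
            raise ValueError("reflection coefficient must be in [0, 1]")
        if r == 0.0:
            continue
        a = np.asarray(itf["p0"], dtype=float)
        b = np.asarray(itf["p1"], dtype=float)
        tang = b - a
        L = np.linalg.norm(tang)
        if L == 0:
            raise ValueError("degenerate interface segment")
        tang = tang / L
        normal = np.array([-tang[1], tang[0]])
        s_ref = (probe_ref - a) @ normal
        s = (centers - a) @ normal          # signed distance to the line
        u = (centers - a) @ tang            # position along the segment
        probe_side = (np.sign(s) == np.sign(s_ref)) & (np.abs(s) > 1e-12)
        sel = probe_side & (u >= 0) & (u <= L) & (vals != 0)
        if not np.any(sel):
            continue
        mirrored = centers[sel] - 2.0 * s[sel, None] * normal[None, :]
        ix = np.rint((mirrored[:, 0] - grid.origin_mm[0]) / grid.pitch_mm).astype(int)
        iz = np.rint((mirrored[:, 1] - grid.origin_mm[1]) / grid.pitch_mm).astype(int)
        ok = (ix >= 0) & (ix < nx) & (iz >= 0) & (iz < nz)
        np.add.at(out, (iz[ok], ix[ok]), r * vals[sel][ok])
    return out
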