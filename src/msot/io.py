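"""HDF5 persistence for sinograms, image stacks, and unmixing results.

Layouts:
  sinogram file:  /sinogram (float32, lam x elem x sample), /wavelengths_nm,
                  /geometry/* attrs, /phantom/concentration/<chromophore>,
                  /phantom/ground_truth/* (masks)
  image file:     /image (lam x z x x), /wavelengths_nm, /recon/provenance
  unmix file:     /unmix/coeffs, /unmix/spectra, /unmix/rel_mse
"""
from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np

from .geometry import ArrayGeometry
from .phantom import ImageGrid, Phantom
from .reconstruct import MultispectralImage
from .simulate import MultispectralSinogram
from .spectra import WavelengthGrid

__all__ = ["save_sinogram", "load_sinogram", "save_image", "load_image",
           "save_unmix", "load_unmix"]

_GEOM_FIELDS = ("n_elements", "coverage_deg", "radius_mm", "focus_depth_mm",
                "sampling_rate_mhz", "n_samples", "t0_us", "sos_mm_us")


def _write_geometry(grp: h5py.Group, geom: ArrayGeometry):
    for f in _GEOM_FIELDS:
        grp.attrs[f] = getattr(geom, f)


def _read_geometry(grp: h5py.Group) -> ArrayGeometry:
    kw = {f: grp.attrs[f] for f in _GEOM_FIELDS}
    kw["n_elements"] = int(kw["n_elements"])
    kw["n_samples"] = int(kw["n_samples"])
    return ArrayGeometry(**kw)


def save_sinogram(path, sino: MultispectralSinogram,
                  phantom: Phantom | None = None):
    with h5py.File(path, "w") as f:
        f.create_dataset("sinogram", data=sino.data.astype(np.float32),
                         compression="gzip")
        f.create_dataset("wavelengths_nm", data=sino.grid.values)
        _write_geometry(f.create_group("geometry"), sino.geometry)
        f.attrs["meta"] = json.dumps(sino.meta, default=str)
        if phantom is not None:
            ph = f.create_group("phantom")
            ph.attrs["pitch_mm"] = phantom.grid.pitch_mm
            ph.attrs["origin_mm"] = phantom.grid.origin_mm
            conc = ph.create_group("concentration")
            for name, c in phantom.concentration_maps.items():
                conc.create_dataset(name, data=c.astype(np.float32),
                                    compression="gzip")
            gt = ph.create_group("ground_truth")
            masks = phantom.ground_truth.get("masks", {})
            for name, m in masks.items():
                gt.create_dataset(f"mask_{name}", data=np.asarray(m, bool))
            vessels = phantom.ground_truth.get("vessels", [])
            if vessels:
                gt.create_dataset("vessel_centers_mm", data=np.array(
                    [v["center_mm"] for v in vessels]))
                gt.create_dataset("vessel_diameters_mm", data=np.array(
                    [v["diameter_mm"] for v in vessels]))
                gt.create_dataset("vessel_so2", data=np.array(
                    [v["so2"] for v in vessels]))


def load_sinogram(path) -> MultispectralSinogram:
    with h5py.File(path, "r") as f:
        data = f["sinogram"][()].astype(float)
        grid = WavelengthGrid(tuple(f["wavelengths_nm"][()]))
        geom = _read_geometry(f["geometry"])
        meta = json.loads(f.attrs.get("meta", "{}"))
    return MultispectralSinogram(data=data, grid=grid, geometry=geom, meta=meta)


def save_image(path, img: MultispectralImage):
    with h5py.File(path, "w") as f:
        f.create_dataset("image", data=img.data.astype(np.float32),
                         compression="gzip")
        f.create_dataset("wavelengths_nm", data=img.grid.values)
        g = f.create_group("recon")
        g.attrs["provenance"] = json.dumps(img.provenance, default=str)
        g.attrs["pitch_mm"] = img.image_grid.pitch_mm
        g.attrs["origin_mm"] = img.image_grid.origin_mm
        g.attrs["shape"] = img.image_grid.shape


def load_image(path) -> MultispectralImage:
    with h5py.File(path, "r") as f:
        data = f["image"][()].astype(float)
        grid = WavelengthGrid(tuple(f["wavelengths_nm"][()]))
        g = f["recon"]
        igrid = ImageGrid(shape=tuple(int(v) for v in g.attrs["shape"]),
                          pitch_mm=float(g.attrs["pitch_mm"]),
                          origin_mm=tuple(g.attrs["origin_mm"]))
        prov = json.loads(g.attrs["provenance"])
    return MultispectralImage(data=data, grid=grid, image_grid=igrid,
                              provenance=prov)


def save_unmix(path, result):
    with h5py.File(path, "w") as f:
        g = f.create_group("unmix")
        g.create_dataset("coeffs", data=result.coefficient_maps.astype(np.float32),
                         compression="gzip")
        g.create_dataset("spectra", data=result.spectra)
        g.attrs["rel_mse"] = result.rel_mse_percent
        g.attrs["mode"] = result.mode
        if result.component_names:
            g.attrs["component_names"] = list(result.component_names)
        g.attrs["alpha_l1"] = result.alpha_l1
        g.attrs["beta_l2"] = result.beta_l2
        if result.seed is not None:
            g.attrs["seed"] = result.seed


def load_unmix(path):
    from .unmix import UnmixResult
    with h5py.File(path, "r") as f:
        g = f["unmix"]
        names = g.attrs.get("component_names")
        return UnmixResult(
            coefficient_maps=g["coeffs"][()].astype(float),
            spectra=g["spectra"][()].astype(float),
            rel_mse_percent=float(g.attrs["rel_mse"]),
            mode=str(g.attrs["mode"]),
            component_names=tuple(names) if names is not None else None,
            alpha_l1=float(g.attrs["alpha_l1"]),
            beta_l2=float(g.attrs["beta_l2"]),
            seed=int(g.attrs["seed"]) if "seed" in g.attrs else None,
        )
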