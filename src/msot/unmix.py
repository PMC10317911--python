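"""Spectral unmixing of reconstructed multispectral image stacks.

Linear mode fits every pixel spectrum to the literature reference spectra by
non-negative least squares. Blind mode factorises the pixels-by-wavelengths
matrix X into non-negative coefficients H and spectra W,

    min_{H,W >= 0}  1/2 ||X - H W^T||_F^2 + alpha ||H||_1 + beta ||W||_F^2,

i.e. sparsity on the per-pixel contributions of the absorbers and an L2
penalty on the spectra to suppress high-frequency noise, solved by
multiplicative updates from an NNDSVD initialisation. The residual metric is
the share of image energy the factorisation leaves unexplained
(``rel_mse_percent``), and blind components are linked to chromophores by
greedy cosine-similarity matching.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .reconstruct import MultispectralImage
from .spectra import ReferenceMatrix, cosine_similarity

__all__ = ["UnmixResult", "ComponentMatch", "linear_unmix", "blind_unmix",
           "relative_mse", "match_components", "so2_from_result"]

_EPS = 1e-12


@dataclass
class UnmixResult:
    coefficient_maps: np.ndarray       # (n_components, nz, nx), >= 0
    spectra: np.ndarray                # (n_wavelengths, n_components), >= 0
    rel_mse_percent: float
    mode: str                          # "linear" | "blind"
    component_names: tuple | None = None
    alpha_l1: float = 0.0
    beta_l2: float = 0.0
    seed: int | None = None
    converged: bool = True
    objectives: list = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.coefficient_maps < 0) or np.any(self.spectra < 0):
            raise ValueError("unmixing factors must be non-negative")
        if self.rel_mse_percent < 0:
            raise ValueError("rel_mse_percent must be >= 0")


@dataclass
class ComponentMatch:
    assignment: dict                   # chromophore -> component index
    scores: dict                       # chromophore -> cosine similarity


def _as_pixel_matrix(images: MultispectralImage) -> np.ndarray:
    d = images.data
    return d.reshape(d.shape[0], -1).T          # (n_pixels, n_wavelengths)


def _rel_mse_percent(X: np.ndarray, Xhat: np.ndarray) -> float:
    denom = float(np.sum(X ** 2))
    if denom == 0:
        return 0.0
    return 100.0 * float(np.sum((X - Xhat) ** 2)) / denom


def linear_unmix(images: MultispectralImage, refs: ReferenceMatrix) -> UnmixResult:
    """Per-pixel NNLS fit of the pixel spectra to the reference columns."""
    if images.grid.wavelengths != refs.grid.wavelengths:
        raise ValueError("image and reference wavelength grids differ")
    X = _as_pixel_matrix(images)                 # (P, L)
    M = refs.matrix                              # (L, K)
    K = M.shape[1]
    H = np.zeros((X.shape[0], K))
    nonzero = np.flatnonzero(np.any(X != 0, axis=1))
    for p in nonzero:
        H[p], _ = nnls(M, X[p])
    Xhat = H @ M.T
    nz, nx = images.image_grid.shape
    return UnmixResult(
        coefficient_maps=H.T.reshape(K, nz, nx),
        spectra=M.copy(),
        rel_mse_percent=_rel_mse_percent(X, Xhat),
        mode="linear",
        component_names=refs.chromophores,
    )


def _nndsvd_init(X: np.ndarray, k: int, rng: np.random.Generator):
    """Non-negative double SVD initialisation (zero entries filled with
    seed-controlled small positives)."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    P, L = X.shape
    H = np.zeros((P, k))
    W = np.zeros((L, k))
    for j in range(min(k, s.size)):
        u, v = U[:, j], Vt[j]
        if j == 0:
            u, v = np.abs(u), np.abs(v)
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        mp = np.linalg.norm(up) * np.linalg.norm(vp)
        mn = np.linalg.norm(un) * np.linalg.norm(vn)
        if mp >= mn and mp > 0:
            h, w, sig = up / np.linalg.norm(up), vp / np.linalg.norm(vp), mp
        elif mn > 0:
            h, w, sig = un / np.linalg.norm(un), vn / np.linalg.norm(vn), mn
        else:
            continue
        H[:, j] = np.sqrt(s[j] * sig) * h
        W[:, j] = np.sqrt(s[j] * sig) * w
    mean = X.mean() if X.size else 0.0
    fill = max(mean / 100.0, 1e-6)
    H[H <= 0] = fill * rng.uniform(0.5, 1.5, size=int((H <= 0).sum()))
    W[W <= 0] = fill * rng.uniform(0.5, 1.5, size=int((W <= 0).sum()))
    return H, W


def blind_unmix(images: MultispectralImage, k: int = 8, alpha_l1: float = 0.0,
                beta_l2: float = 0.0, seed: int = 0,
                max_iter: int = 500, tol: float = 1e-7) -> UnmixResult:
    """Regularised NMF of the image stack (L1 on coefficients, L2 on spectra).

    Deterministic per seed; the objective is non-increasing over iterations
    and non-convergence within ``max_iter`` is flagged, not raised.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = _as_pixel_matrix(images)
    if k > X.shape[1]:
        raise ValueError("k may not exceed the number of wavelengths")
    if alpha_l1 < 0 or beta_l2 < 0:
        raise ValueError("regularization weights must be >= 0")
    if not np.any(X):
        raise ValueError("cannot factorise an all-zero stack")
    rng = np.random.default_rng(seed)
    H, W = _nndsvd_init(X, k, rng)

    def objective(H, W):
        return (0.5 * np.sum((X - H @ W.T) ** 2)
                + alpha_l1 * np.sum(H) + beta_l2 * np.sum(W ** 2))

    objs = [float(objective(H, W))]
    converged = False
    for _ in range(max_iter):
        WtW = W.T @ W
        H *= (X @ W) / (H @ WtW + alpha_l1 + _EPS)
        HtH = H.T @ H
        W *= (X.T @ H) / (W @ HtH + 2.0 * beta_l2 * W + _EPS)
        f = float(objective(H, W))
        objs.append(f)
        if abs(objs[-2] - f) <= tol * max(abs(objs[-2]), 1e-30):
            converged = True
            break
    nz, nx = images.image_grid.shape
    return UnmixResult(
        coefficient_maps=H.T.reshape(k, nz, nx),
        spectra=W,
        rel_mse_percent=_rel_mse_percent(X, H @ W.T),
        mode="blind", alpha_l1=alpha_l1, beta_l2=beta_l2, seed=seed,
        converged=converged, objectives=objs,
    )


def relative_mse(images: MultispectralImage, result: UnmixResult) -> float:
    """Percent of stack energy unexplained: 100 ||X - Xhat||^2 / ||X||^2."""
    X = _as_pixel_matrix(images)
    if not np.any(X):
        raise ValueError("relative MSE undefined for an all-zero stack")
    k = result.coefficient_maps.shape[0]
    H = result.coefficient_maps.reshape(k, -1).T
    if H.shape[0] != X.shape[0] or result.spectra.shape[0] != X.shape[1]:
        raise ValueError("unmixing result does not match the image stack")
    return _rel_mse_percent(X, H @ result.spectra.T)


def so2_from_result(result: UnmixResult, min_total: float = 1e-6):
    """Oxygen-saturation map from a result with named hemoglobin components."""
    from .analyze import so2_map
    if not result.component_names or \
            not {"hbo2", "hbr"} <= set(result.component_names):
        raise ValueError("result lacks named HbO2/HbR components")
    i_o = result.component_names.index("hbo2")
    i_r = result.component_names.index("hbr")
    return so2_map(result.coefficient_maps[i_o], result.coefficient_maps[i_r],
                   min_total=min_total)


def match_components(result: UnmixResult, refs: ReferenceMatrix) -> ComponentMatch:
    """Greedy assignment of blind components to reference chromophores.

    Pairs are taken in descending cosine similarity; every chromophore is
    matched at most once and to a distinct component.
    """
    if result.mode != "blind":
        raise ValueError("component matching applies to blind-mode results")
    k = result.spectra.shape[1]
    names = refs.chromophores
    if k < len(names):
        raise ValueError("fewer components than chromophores to match")
    sims = np.full((len(names), k), -np.inf)
    for i in range(len(names)):
        for j in range(k):
            col = result.spectra[:, j]
            if np.linalg.norm(col) == 0:
                continue
            sims[i, j] = cosine_similarity(refs.matrix[:, i], col)
    assignment, scores = {}, {}
    used_comp: set = set()
    order = np.argsort(sims, axis=None)[::-1]
    for flat in order:
        i, j = np.unravel_index(flat, sims.shape)
        if names[i] in assignment or j in used_comp or not np.isfinite(sims[i, j]):
            continue
        assignment[names[i]] = int(j)
        scores[names[i]] = float(sims[i, j])
        used_comp.add(int(j))
        if len(assignment) == len(names):
            break
    return ComponentMatch(assignment=assignment, scores=scores)
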