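"""Ab initio molecular-envelope reconstruction.

The protein mask is rebuilt during iteration from the current density: the
map is smoothed with a periodic Gaussian of standard deviation ``sigma``
(Angstrom) and thresholded so that the highest-weight fraction
``1 - solvent_fraction`` of voxels forms the protein region.  ``sigma``
follows a coarse-to-fine linear schedule from 4.0 A to 2.5 A, capturing the
approximate envelope early and refining the boundary later.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.fft as _fft

from .core import DensityMap, Mask

__all__ = [
    "gaussian_weights",
    "gaussian_weights_grid",
    "sigma_schedule",
    "mask_from_weights",
    "mask_from_weights_grid",
    "mask_iou",
]


def _gauss_transfer(grid_s2: np.ndarray, sigma: float) -> np.ndarray:
    """Reciprocal-space transfer function of a normalized Gaussian kernel."""
    return np.exp(-2.0 * np.pi**2 * sigma**2 * grid_s2)


def gaussian_weights_grid(
    values: np.ndarray, grid_s2: np.ndarray, sigma: float
) -> np.ndarray:
    """Periodic convolution with a normalized Gaussian (reciprocal space).

    ``grid_s2`` holds |s|^2 per Fourier coefficient, either for the full
    spectrum or for the rfftn half spectrum of ``values``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    t = _gauss_transfer(grid_s2, sigma)
    if np.all(t[grid_s2 > 0] < 1e-300):
        warnings.warn("Gaussian kernel underflows the grid; returning input")
        return values.copy()
    if grid_s2.size == values.size:
        F = np.fft.fftn(values)
        return np.fft.ifftn(F * t.reshape(values.shape)).real
    F = _fft.rfftn(values)
    return _fft.irfftn(F * t.reshape(F.shape), values.shape)


def gaussian_weights(dmap: DensityMap, sigma: float) -> DensityMap:
    """Gaussian-weighted average w_n of the density (kernel sd in Angstrom).

    Constant maps are fixed points: the kernel is normalized (transfer 1 at
    s = 0), so adding a constant to the map adds the same constant to w_n.
    """
    grid = dmap.grid
    hs = [np.fft.fftfreq(n, 1.0 / n) for n in grid]
    hh, kk, ll = np.meshgrid(*hs, indexing="ij")
    hkl = np.stack([hh.ravel(), kk.ravel(), ll.ravel()], axis=1)
    gstar = dmap.cell.reciprocal_metric()
    s2 = np.einsum("ni,ij,nj->n", hkl, gstar, hkl)
    return DensityMap(gaussian_weights_grid(dmap.values, s2, sigma), dmap.cell)


def sigma_schedule(
    it: int, n_iter: int, sigma_start: float = 4.0, sigma_end: float = 2.5
) -> float:
    """Linear envelope-smoothing schedule from sigma_start to sigma_end.

    Reaches ``sigma_end`` at the last envelope update (iteration n_iter - 1)
    and stays there for any later iteration.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if n_iter == 1:
        return float(sigma_end)
    frac = min(max(it, 0), n_iter - 1) / (n_iter - 1)
    return float(sigma_start + (sigma_end - sigma_start) * frac)


def mask_from_weights_grid(w: np.ndarray, solvent_fraction: float) -> np.ndarray:
    """Boolean protein mask: top (1 - solvent_fraction) voxels by weight.

    The threshold is the corresponding order statistic; ties are broken
    deterministically by flattened voxel index (stable sort), so the mask is
    invariant under adding a constant to w or scaling it by c > 0.
    """
    if not 0.0 < solvent_fraction < 1.0:
        raise ValueError("solvent_fraction must lie in (0, 1)")
    flat = w.ravel()
    n = flat.size
    n_prot = int(round((1.0 - solvent_fraction) * n))
    n_prot = min(max(n_prot, 1), n - 1)
    order = np.argsort(-flat, kind="stable")
    inside = np.zeros(n, dtype=bool)
    inside[order[:n_prot]] = True
    return inside.reshape(w.shape)


def mask_from_weights(w: DensityMap, solvent_fraction: float) -> Mask:
    return Mask(mask_from_weights_grid(w.values, solvent_fraction), w.cell)


def mask_iou(a: Mask, b: Mask) -> float:
    """Intersection over union of two protein masks; 1.0 if both empty."""
    if a.grid != b.grid:
        raise ValueError("masks live on different grids")
    inter = np.logical_and(a.inside, b.inside).sum()
    union = np.logical_or(a.inside, b.inside).sum()
    if union == 0:
        return 1.0
    return float(inter / union)
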