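"""Origin-shift / enantiomer alignment shared by metrics, GA and averaging.

Iterates are re-symmetrized after every real-space projection, so the
space-group rotations act as identities on them; the residual degeneracy of a
phasing solution is an allowed origin shift (continuous along polar axes,
discrete otherwise) plus, in non-centrosymmetric space groups, an inversion
of the map through the origin.  The search maximizes the real-space overlap
computed by FFT cross-correlation, with parabolic sub-voxel refinement along
polar axes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.fft as _fft

from .core import SpaceGroupInfo

__all__ = ["Alignment", "best_alignment", "apply_alignment_grid", "invert_grid"]


@dataclasses.dataclass(frozen=True)
class Alignment:
    """A rigid transform in the solution-degeneracy group."""

    shift: tuple[float, float, float]  # fractional, applied after inversion
    inverted: bool
    score: float


def invert_grid(values: np.ndarray) -> np.ndarray:
    """Map rho(r) -> rho(-r) on the periodic voxel grid."""
    out = values[::-1, ::-1, ::-1]
    return np.roll(out, 1, axis=(0, 1, 2))


def _allowed_position_mask(
    sg: SpaceGroupInfo, grid: tuple[int, int, int]
) -> np.ndarray | None:
    """Boolean mask of allowed shift positions; None means all allowed."""
    if all(sg.polar_axes):
        return None
    mask = np.zeros(grid, dtype=bool)
    for shift in sg.allowed_origin_shifts:
        sel = []
        ok = True
        for k, n in enumerate(grid):
            if sg.polar_axes[k]:
                sel.append(np.arange(n))
            else:
                pos = shift[k] * n
                if abs(pos - round(pos)) > 1e-6:
                    ok = False
                    break
                sel.append(np.array([int(round(pos)) % n]))
        if ok:
            mask[np.ix_(sel[0], sel[1], sel[2])] = True
    return mask


def _parabolic(cm: float, c0: float, cp: float) -> float:
    den = cm - 2.0 * c0 + cp
    if abs(den) < 1e-300:
        return 0.0
    return float(np.clip(0.5 * (cm - cp) / den, -0.5, 0.5))


def _best_in_volume(
    corr: np.ndarray,
    sg: SpaceGroupInfo,
    allowed: np.ndarray | None,
) -> tuple[tuple[float, float, float], float]:
    grid = corr.shape
    if allowed is None:
        flat = int(np.argmax(corr))
    else:
        masked = np.where(allowed, corr, -np.inf)
        flat = int(np.argmax(masked))
    idx = np.unravel_index(flat, grid)
    shift = []
    for k, n in enumerate(grid):
        x = float(idx[k])
        if sg.polar_axes[k]:
            cm = corr[tuple(np.mod(np.add(idx, -np.eye(3, dtype=int)[k]), grid))]
            cp = corr[tuple(np.mod(np.add(idx, np.eye(3, dtype=int)[k]), grid))]
            x += _parabolic(float(cm), float(corr[idx]), float(cp))
        shift.append((x / n) % 1.0)
    return tuple(shift), float(corr[idx])


def best_alignment(
    Fh_ref: np.ndarray,
    Fh_mov: np.ndarray,
    sg: SpaceGroupInfo,
    grid: tuple[int, int, int],
    try_inversion: bool | None = None,
) -> Alignment:
    """Transform of ``mov`` maximizing overlap with ``ref``.

    Both arguments are half-spectrum (rfftn) coefficient arrays of real
    densities on ``grid``.  The returned shift means: apply inversion first
    (if flagged), then translate by ``shift`` (fractional), i.e.
    ``rho_aligned(x) = rho_mov_maybe_inverted(x - shift)``.
    """
    if try_inversion is None:
        try_inversion = sg.has_inversion_ambiguity
    allowed = _allowed_position_mask(sg, grid)
    G = Fh_ref * np.conj(Fh_mov)
    G.reshape(-1)[0] = 0.0  # mean offset does not discriminate shifts
    corr = _fft.irfftn(G, grid)
    shift, score = _best_in_volume(corr, sg, allowed)
    best = Alignment(shift=shift, inverted=False, score=score)
    if try_inversion:
        Gi = Fh_ref * Fh_mov  # conj(conj(F_mov)) for the inverted map
        Gi.reshape(-1)[0] = 0.0
        corr_i = _fft.irfftn(Gi, grid)
        shift_i, score_i = _best_in_volume(corr_i, sg, allowed)
        if score_i > score:
            best = Alignment(shift=shift_i, inverted=True, score=score_i)
    return best


def _shift_phases_half(grid: tuple[int, int, int], shift) -> np.ndarray:
    hs = [
        np.fft.fftfreq(grid[0], 1.0 / grid[0]),
        np.fft.fftfreq(grid[1], 1.0 / grid[1]),
        np.arange(grid[2] // 2 + 1),
    ]
    phases = [np.exp(-2j * np.pi * h * shift[k]) for k, h in enumerate(hs)]
    return (
        phases[0][:, None, None] * phases[1][None, :, None] * phases[2][None, None, :]
    )


def apply_alignment_grid(values: np.ndarray, alignment: Alignment) -> np.ndarray:
    """Apply an alignment to a real density grid (Fourier shift, sub-voxel)."""
    v = invert_grid(values) if alignment.inverted else values
    F = _fft.rfftn(v)
    return _fft.irfftn(F * _shift_phases_half(v.shape, alignment.shift), v.shape)


def transform_refl_sf(
    f: np.ndarray, hkl: np.ndarray, alignment: Alignment
) -> np.ndarray:
    """Apply an alignment to per-reflection structure factors."""
    g = np.conj(f) if alignment.inverted else f
    return g * np.exp(-2j * np.pi * (hkl @ np.asarray(alignment.shift)))
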