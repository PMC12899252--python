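"""Quantitative assessment of phasing runs.

R factors compare observed and scaled calculated amplitudes,

    R = sum | |Fobs| - lambda |Fcal| | / sum |Fobs|,

with lambda = sum_work |Fobs| / sum_work |Fcal| always taken over the work
set (also when scoring the free set).  The mean phase error is the average
absolute circular difference between retrieved and reference phases over the
work set; random phases score 90 degrees in expectation.  The regional
density deviations monitor, without any reference information, the mean
absolute value of each algorithm's own relaxation term over the protein
region and of the negative-feedback density PB(rho) over the solvent.
"""

from __future__ import annotations

import numpy as np

from . import _align
from .core import ComplexSF, GridContext, ReflectionSet
from .projections import scale_factor

__all__ = [
    "r_factor",
    "mean_phase_error",
    "aligned_phase_error",
    "density_deviation_from_cache",
    "DEVIATION_BRACKETS",
]


def r_factor(rs: ReflectionSet, sf: ComplexSF, subset: str = "work") -> float:
    """Rwork or Rfree for calculated structure factors."""
    if subset == "work":
        sel = rs.work
    elif subset == "free":
        sel = rs.free
    else:
        raise ValueError("subset must be 'work' or 'free'")
    if not np.any(sel):
        raise ValueError(f"empty {subset} subset")
    lam = scale_factor(rs, sf)
    num = np.abs(rs.f_obs[sel] - lam * sf.amplitude[sel]).sum()
    den = rs.f_obs[sel].sum()
    if den <= 0:
        raise ValueError(f"{subset} subset has zero total amplitude")
    return float(num / den)


def mean_phase_error(
    rs: ReflectionSet, phi_true: ComplexSF, phi_cal: ComplexSF
) -> float:
    """Mean phase error (degrees) over the work set, in [0, 180].

    Computed as arccos(cos(dphi)) per reflection, which is symmetric in its
    arguments and invariant under adding full turns to either phase.  Note
    that in space groups with a floating origin this raw comparison is only
    meaningful for phases referred to the same origin; see
    :func:`aligned_phase_error`.
    """
    work = rs.work
    if not np.any(work):
        raise ValueError("empty work set")
    ft = phi_true.f[work]
    fc = phi_cal.f[work]
    if np.any(np.abs(ft) == 0) or np.any(np.abs(fc) == 0):
        raise ValueError("phase undefined for zero-amplitude reflection")
    dphi = np.angle(ft * np.conj(fc))
    return float(np.degrees(np.abs(dphi)).mean())


def aligned_phase_error(
    ctx: GridContext,
    F_true: np.ndarray,
    F_cal: np.ndarray,
) -> tuple[float, _align.Alignment]:
    """Mean phase error after searching allowed origin shifts / inversion.

    ``F_true`` and ``F_cal`` are half-spectrum (rfftn) coefficient arrays.
    Returns the error (degrees, work set) and the alignment applied to the
    calculated map.  This is the quantity recorded in the run trace: with a
    floating origin the raw phase difference is arbitrary, so the calculated
    phases are first referred to the reference origin.
    """
    rs = ctx.rs
    al = _align.best_alignment(F_true, F_cal, ctx.sg, ctx.grid)
    f_cal0 = ctx.rgather(F_cal)
    f_true = ctx.rgather(F_true)
    work = rs.work
    polar = np.array(ctx.sg.polar_axes)

    def residual(alignment):
        f_cal = _align.transform_refl_sf(f_cal0, rs.hkl, alignment)
        return np.angle(f_true * np.conj(f_cal))

    # least-squares sub-voxel origin refinement along polar axes: the
    # residual phases of a well-aligned solution obey dphi ~ -2 pi h.eps
    if polar.any():
        for _ in range(2):
            dphi = residual(al)
            w = np.abs(f_true) * np.abs(f_cal0)
            sel = work & (np.abs(dphi) < np.pi / 2)
            H = rs.hkl[sel][:, polar].astype(float)
            if len(H) > 10:
                A = -2.0 * np.pi * H * w[sel][:, None]
                b = dphi[sel] * w[sel]
                eps, *_ = np.linalg.lstsq(A, b, rcond=None)
                shift = np.array(al.shift)
                shift[polar] += eps
                al = _align.Alignment(tuple(shift % 1.0), al.inverted, al.score)
    dphi = residual(al)[work]
    return float(np.degrees(np.abs(dphi)).mean()), al


#: protein-region relaxation bracket monitored for each update rule, written
#: in terms of the cached evaluations PA(rho), PB(rho), PA(PB(rho)).
DEVIATION_BRACKETS = {
    "diffmap": "2papb-pa-pb",
    "hio": "papb-rho",
    "hdm_f1": "2papb-pa-pb",
    "hdm_f2": "2papb-pa-pb",
    "hdm_f3": "papb-pa",
    "hdm_f4": "papb-pa",
    "hdm_f5": "papb-pb",
    "hdm_f6": "papb-pb",
}


def density_deviation_from_cache(
    algorithm: str,
    inside: np.ndarray,
    cache: dict,
) -> tuple[float, float]:
    """Regional density deviations (protein, solvent) from cached operators.

    ``cache`` holds the step's own evaluations under keys ``rho``, ``pb``,
    ``papb`` and (for rules that use it) ``pa``.  The solvent-side deviation
    is the mean |PB rho| over solvent voxels.
    """
    bracket = DEVIATION_BRACKETS[algorithm]
    rho = cache["rho"]
    pb = cache["pb"]
    papb = cache["papb"]
    if bracket == "2papb-pa-pb":
        term = 2.0 * papb - cache["pa"] - pb
    elif bracket == "papb-pa":
        term = papb - cache["pa"]
    elif bracket == "papb-pb":
        term = papb - pb
    elif bracket == "papb-rho":
        term = papb - rho
    else:  # pragma: no cover
        raise ValueError(bracket)
    dev_protein = float(np.abs(term[inside]).mean())
    dev_solvent = float(np.abs(pb[~inside]).mean())
    return dev_protein, dev_solvent
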