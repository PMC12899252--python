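"""The two projection operators at the heart of iterative phasing.

``project_real`` (PA) enforces the real-space constraints: density in the
solvent region is flattened to zero and the protein-region density is
rank-order remapped onto a reference histogram of protein density at the
working resolution.  ``project_fourier`` (PB) enforces the experimental data:
the calculated Fourier amplitudes of the working reflections are replaced by
the (optionally resolution-weighted) observed amplitudes while the calculated
phases are retained.

Reflections that carry no usable observation -- the free set, missing,
large-error and low-resolution reflections -- keep their calculated
amplitudes, which is the missing-amplitude fill rule
|Fmiss| = (sum|Fobs| / sum|Fcal|) |Fcal| expressed on the calculated scale.
Fourier coefficients outside the measured band are set to zero (the density
model is band-limited to the data), while F(000) is passed through: the
absolute offset is unobservable and the real-space constraints pin it.
Both operators are idempotent.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .core import ComplexSF, DensityMap, GridContext, Mask, ReflectionSet

__all__ = [
    "HistogramRef",
    "scale_factor",
    "fill_missing",
    "project_fourier",
    "project_real",
    "make_reference_histogram",
]


@dataclasses.dataclass
class HistogramRef:
    """Ordered quantiles sampling the reference CDF of protein density.

    ``quantiles[j]`` is the density value at cumulative probability
    ``(j + 0.5) / len(quantiles)``.
    """

    resolution: float
    quantiles: np.ndarray

    def __post_init__(self) -> None:
        self.quantiles = np.asarray(self.quantiles, dtype=float).ravel()
        if len(self.quantiles) < 2:
            raise ValueError("need at least 2 quantiles")
        if np.any(np.diff(self.quantiles) < -1e-12):
            raise ValueError("quantiles must be monotone non-decreasing")

    def save(self, path) -> None:
        lines = [f"# resolution {self.resolution:.6g}"]
        lines += [f"{j} {float(q)!r}" for j, q in enumerate(self.quantiles)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "HistogramRef":
        res = 0.0
        vals = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line.startswith("#"):
                if "resolution" in line:
                    res = float(line.split()[-1])
                continue
            if line:
                vals.append(float(line.split()[1]))
        return cls(resolution=res, quantiles=np.array(vals))


def make_reference_histogram(
    model_map: DensityMap, mask: Mask, n_quantiles: int
) -> HistogramRef:
    """Quantiles of the protein-region density of a model map.

    Protein electron-density histograms at a given resolution are remarkably
    similar across structures, so a histogram from any model of comparable
    resolution serves as a transferable real-space constraint.
    """
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    if mask.inside.shape != model_map.values.shape:
        raise ValueError("mask grid does not match map grid")
    vals = np.sort(model_map.values[mask.inside])
    if len(vals) == 0:
        raise ValueError("empty protein region")
    n = len(vals)
    p_data = (np.arange(n) + 0.5) / n
    p_q = (np.arange(n_quantiles) + 0.5) / n_quantiles
    q = np.interp(p_q, p_data, vals)
    return HistogramRef(resolution=0.0, quantiles=q)


def scale_factor(rs: ReflectionSet, sf: ComplexSF) -> float:
    """Amplitude scale lambda = sum_work |Fobs| / sum_work |Fcal|."""
    work = rs.work
    if not np.any(work) or rs.f_obs[work].sum() <= 0:
        raise ValueError("need at least one work reflection with Fobs > 0")
    denom = sf.amplitude[work].sum()
    if denom <= 0:
        raise ValueError("degenerate input: all calculated amplitudes vanish")
    return float(rs.f_obs[work].sum() / denom)


def fill_missing(rs: ReflectionSet, sf: ComplexSF) -> np.ndarray:
    """Fill amplitudes for all non-work reflections from calculated values,
    |Fmiss(h)| = (sum_work |Fobs| / sum_work |Fcal|) * |Fcal(h)|.

    Returns an amplitude per reflection: observed for the work set, filled
    for everything else (on the observed scale)."""
    lam = scale_factor(rs, sf)
    amp = sf.amplitude
    return np.where(rs.work, rs.f_obs, lam * amp)


def project_fourier(
    dmap: DensityMap,
    rs: ReflectionSet,
    weights: np.ndarray | None = None,
    ctx: GridContext | None = None,
) -> DensityMap:
    """PB: impose (weighted) observed amplitudes, keep calculated phases."""
    ctx = ctx or GridContext(rs, dmap.grid)
    values, _ = project_fourier_grid(dmap.values, ctx, weights)
    return DensityMap(values, dmap.cell)


def project_fourier_grid(
    values: np.ndarray,
    ctx: GridContext,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Grid-level PB used by every iterator (single source of truth).

    Returns the projected density and a cache holding the full coefficient
    array, the per-reflection calculated structure factors and the internal
    scale, so callers can reuse them for metrics without extra transforms.
    """
    rs = ctx.rs
    F = ctx.rsf_grid(values)
    flat = F.ravel()
    f_refl = ctx.rgather(F)
    amp_refl = np.abs(f_refl)
    work = rs.work
    if weights is None:
        w = np.ones(len(rs))
    else:
        w = np.asarray(weights, dtype=float)
    obs_w = w * rs.f_obs
    denom = amp_refl[work].sum()
    num = obs_w[work].sum()
    if denom <= 0 or num <= 0:
        raise ValueError("degenerate input: calculated amplitudes vanish")
    lam = num / denom  # weighted-data scale; the ratio-of-sums lambda when w == 1
    # target amplitude on the calculated scale; non-work keeps |Fcal|
    target = np.where(work, obs_w / lam, amp_refl)

    cid = ctx.half_coeff_refl_id
    sel = np.nonzero(cid >= 0)[0]
    t_coeff = target[cid[sel]]
    cur = flat[sel]
    a_coeff = np.abs(cur)
    ratio = np.where(a_coeff > 0, t_coeff / np.where(a_coeff > 0, a_coeff, 1.0), 0.0)
    newvals = cur * ratio
    # zero calculated amplitude: phase undefined, take phase 0 by convention
    newvals = np.where(a_coeff > 0, newvals, t_coeff.astype(complex))
    out = np.zeros_like(flat)  # out-of-band content is not part of the model
    out[sel] = newvals
    out[0] = flat[0]  # F(000): unobservable offset, passed through
    cache = {
        "fcal": ComplexSF(rs.hkl, f_refl),
        "lambda_pb": lam,
        "F_half": F,
    }
    return ctx.rdensity_grid(out.reshape(ctx.half_shape)), cache


def project_real(
    dmap: DensityMap, mask: Mask, href: HistogramRef
) -> DensityMap:
    """PA: flatten solvent to zero, histogram-match the protein region."""
    return DensityMap(
        project_real_grid(dmap.values, mask.inside, href), dmap.cell
    )


def project_real_grid(
    values: np.ndarray, inside: np.ndarray, href: HistogramRef
) -> np.ndarray:
    """Grid-level PA shared by all iterators.

    Protein voxels are ranked (stable sort, ties broken by flattened voxel
    index) and mapped onto the reference quantiles by inverse-CDF
    interpolation; solvent voxels are set to exactly zero.
    """
    if inside.shape != values.shape:
        raise ValueError("mask grid does not match map grid")
    n_prot = int(inside.sum())
    if n_prot == 0:
        raise ValueError("empty protein region")
    out = np.zeros_like(values)
    prot = values[inside]
    # ties are broken by flattened voxel index; the fast introsort result is
    # only revisited when ties actually occur (rare for continuous iterates)
    order = np.argsort(prot)
    if np.any(prot[order[1:]] == prot[order[:-1]]):
        order = np.argsort(prot, kind="stable")
    m = len(href.quantiles)
    p_rank = (np.arange(n_prot) + 0.5) / n_prot
    p_q = (np.arange(m) + 0.5) / m
    mapped = np.interp(p_rank, p_q, href.quantiles)
    new_prot = np.empty(n_prot)
    new_prot[order] = mapped
    out[inside] = new_prot
    return out
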