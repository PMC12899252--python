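"""Toy-crystal fixtures with exact amplitudes and known true phases.

A toy crystal is a cluster of Gaussian pseudo-atoms in a periodic unit cell.
The generator builds the density directly in reciprocal space (each blob's
transform is an analytic Gaussian), flattens the solvent and band-limits the
result to the working resolution.  The returned amplitudes are |F| of that
true map exactly, so the data are noise-free and the truth phases are
self-consistent; the solvent region of the band-limited true map carries the
small series-termination ripple real solvent-flattened maps show.

With ``exact_fixed_point=True`` the generator instead solves for a map that
is *simultaneously* band-limited and exactly flat in the solvent (plus
histogram-locked in the protein region), making it an exact common fixed
point of both projection operators -- the anchor for the operator-algebra
tests.  Such a map only exists when the real degrees of freedom in the
measured band exceed the number of solvent voxels, i.e. at low solvent
fraction on a near-Nyquist grid, which is why the exact fixture uses a
smaller, protein-rich crystal.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as _fft

from .core import (
    ComplexSF,
    DensityMap,
    GridContext,
    Mask,
    ReflectionSet,
    SpaceGroupInfo,
    Status,
    UnitCell,
    choose_grid,
    reduce_to_asu,
    rng_for,
)
from .envelope import gaussian_weights_grid, mask_from_weights_grid
from .projections import HistogramRef, make_reference_histogram, project_real_grid

__all__ = ["ToyCrystal", "make_toy_crystal", "add_noise"]


class ToyCrystal:
    """Bundle returned by :func:`make_toy_crystal`; unpacks as
    (reflections, truth, true_map, true_mask, href)."""

    def __init__(self, rs, truth, true_map, true_mask, href, ctx):
        self.rs: ReflectionSet = rs
        self.truth: ComplexSF = truth
        self.true_map: DensityMap = true_map
        self.true_mask: Mask = true_mask
        self.href: HistogramRef = href
        self.ctx: GridContext = ctx

    def __iter__(self):
        return iter((self.rs, self.truth, self.true_map, self.true_mask, self.href))


def _blob_structure_factors(
    ctx: GridContext,
    cell: UnitCell,
    sg: SpaceGroupInfo,
    centers: np.ndarray,
    widths: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    """Full-grid coefficients of a symmetrized sum of Gaussian blobs."""
    # expand centers over the symmetry operations
    xs = []
    for rot, tran in sg.symops:
        xs.append((centers @ rot.T + tran) % 1.0)
    xs = np.concatenate(xs, axis=0)
    widths = np.tile(widths, sg.n_ops)
    weights = np.tile(weights, sg.n_ops) / sg.n_ops
    hkl = ctx.grid_hkl.astype(float)
    s2 = ctx.grid_s2
    # F(h) = sum_j w_j exp(-2 pi^2 sigma_j^2 s^2) exp(-2 pi i h.x_j)
    F = np.zeros(len(s2), dtype=complex)
    for x, sig, w in zip(xs, widths, weights):
        F += w * np.exp(-2.0 * np.pi**2 * sig * sig * s2 - 2j * np.pi * (hkl @ x))
    return F.reshape(ctx.grid)


def make_toy_crystal(
    cell: UnitCell | None = None,
    sg: SpaceGroupInfo | str = "P 1",
    n_blobs: int = 28,
    solvent_fraction: float = 0.70,
    d_min: float = 2.0,
    seed: int = 0,
    grid_spacing: float | None = None,
    blob_width: tuple[float, float] = (0.65, 0.9),
    mask_sigma: float = 2.5,
    exact_fixed_point: bool = False,
) -> ToyCrystal:
    """Generate a toy crystal with exact data and self-consistent truth.

    Blob centers are drawn inside a sphere whose volume matches the requested
    protein fraction (or uniformly, when protein occupies most of the cell),
    giving a compact molecule with real protein/solvent contrast.  Blob
    widths are Gaussian sigmas in Angstrom; the defaults emulate atoms
    broadened by typical crystallographic displacement at ~2 A resolution.
    The returned reflection set holds |Fobs| = |F(true map)| exactly (sigma
    0, all work); the true map is band-limited to d >= d_min, and its F(000)
    carries the positive protein/solvent offset.
    """
    if cell is None:
        cell = UnitCell(30.0, 30.0, 30.0)
    if isinstance(sg, str):
        sg = SpaceGroupInfo.from_symbol(sg)
    if not 0.0 < solvent_fraction < 1.0:
        raise ValueError("solvent_fraction must lie in (0, 1)")
    rng = rng_for(seed, "toy")
    spacing = grid_spacing if grid_spacing is not None else d_min / 3.0
    grid = choose_grid(cell, sg, spacing, d_min)

    # enumerate unique reflections representable on the grid with d >= d_min
    probe = _probe_context(cell, sg, grid)
    smax = 1.0 / d_min
    lim = np.array(grid) // 2
    sel = (
        (probe.grid_s2 <= smax * smax + 1e-12)
        & (np.abs(probe.grid_hkl) < lim[None, :]).all(axis=1)
        & np.any(probe.grid_hkl != 0, axis=1)
    )
    hkl = probe.grid_hkl[sel]
    canon = reduce_to_asu(hkl, sg)
    uniq = hkl[np.all(hkl == canon, axis=1)]
    order = np.lexsort((uniq[:, 2], uniq[:, 1], uniq[:, 0]))
    uniq = uniq[order]

    # protein ball radius from the requested protein volume
    protein_frac = (1.0 - solvent_fraction) / sg.n_ops
    r_frac = (3.0 * protein_frac / (4.0 * np.pi)) ** (1.0 / 3.0)
    mean_len = float(np.mean(cell.lengths))
    radius = r_frac * mean_len
    if protein_frac >= 0.5:
        # protein-rich cell: no compact ball fits, scatter blobs everywhere
        centers = rng.uniform(0.0, 1.0, size=(n_blobs, 3))
    elif radius > 0.5 * min(cell.lengths):
        raise ValueError(
            "infeasible solvent fraction: protein ball does not fit in the cell"
        )
    else:
        centers = _sphere_points(rng, n_blobs, radius, cell) + 0.5
    widths = rng.uniform(*blob_width, size=n_blobs)
    weights = rng.uniform(0.5, 1.0, size=n_blobs)

    F = _blob_structure_factors(probe, cell, sg, centers % 1.0, widths, weights)
    # band-limit to the measured resolution range
    keep = (probe.grid_s2 <= smax * smax + 1e-12).reshape(grid)
    F = np.where(keep, F, 0.0)
    rho0 = np.fft.ifftn(F).real
    rho0 = probe.symmetrize(rho0)

    # envelope of the raw blob map -> true mask
    w = gaussian_weights_grid(rho0, probe.grid_s2, mask_sigma)
    inside = mask_from_weights_grid(w, solvent_fraction)

    # shift so the protein floor touches the solvent level (positive
    # protein/solvent contrast, offset carried by F(000))
    rho0 = rho0 - rho0[inside].min()

    rs = ReflectionSet(
        cell=cell,
        sg=sg,
        d_min=d_min,
        hkl=uniq,
        f_obs=np.zeros(len(uniq)),
        sig_f=np.zeros(len(uniq)),
        status=np.full(len(uniq), Status.WORK, dtype=np.int8),
    )
    ctx = GridContext(rs, grid)

    # flatten the solvent, then band-limit to exactly the measured
    # coefficient set (plus F(000)); the re-introduced solvent ripple is the
    # series-termination error a real solvent-flattened map carries
    keep_half = ctx.half_coeff_refl_id >= 0
    keep_half[0] = True  # F(000)
    keep_half = keep_half.reshape(ctx.half_shape)
    flat0 = np.where(inside, rho0, 0.0)
    rho_star = _fft.irfftn(np.where(keep_half, _fft.rfftn(flat0), 0.0), grid)

    if exact_fixed_point:
        rho_star = _exact_flat_solvent(rho_star, inside, rs, ctx)
        rho_star = np.where(inside, rho_star, 0.0)
    rho_star = probe.symmetrize(rho_star)
    n_prot = int(inside.sum())

    F_star = ctx.sf_grid(rho_star)
    f_refl = ctx.gather(F_star)
    rs.f_obs = np.abs(f_refl)

    true_map = DensityMap(rho_star, cell)
    true_mask = Mask(inside, cell)
    achieved = true_mask.protein_fraction * 1.0
    if abs(achieved - (1.0 - solvent_fraction)) > 0.05:
        raise ValueError(
            f"infeasible solvent fraction: achieved protein fraction {achieved:.3f}"
        )
    href = make_reference_histogram(true_map, true_mask, n_quantiles=n_prot)
    truth = ComplexSF(rs.hkl, f_refl)
    return ToyCrystal(rs, truth, true_map, true_mask, href, ctx)


def _exact_flat_solvent(
    rho_band: np.ndarray,
    inside: np.ndarray,
    rs: ReflectionSet,
    ctx: GridContext,
) -> np.ndarray:
    """Minimum-norm band-limited correction making the solvent exactly zero.

    The real degrees of freedom of a band-limited map are two per unique
    reflection (cosine and sine modes) plus the F(000) constant; zeroing the
    solvent imposes one constraint per solvent voxel.  The correction exists
    only when modes outnumber constraints -- i.e. for protein-rich crystals
    on a near-Nyquist grid -- and is found by a dense least-norm solve.
    Only P1 fixtures are supported (no symmetry redundancy bookkeeping).
    """
    if rs.sg.n_ops != 1:
        raise ValueError("exact_fixed_point fixtures require space group P 1")
    grid = ctx.grid
    n_modes = 2 * len(rs) + 1
    m = int((~inside).sum())
    if n_modes < m:
        raise ValueError(
            f"no band-limited map is exactly solvent-flat here: {n_modes} "
            f"band modes < {m} solvent voxels (lower the solvent fraction "
            "or refine the grid toward Nyquist)"
        )
    idx = np.argwhere(~inside) / np.array(grid)  # fractional solvent coords
    arg = 2.0 * np.pi * (idx @ rs.hkl.T)  # (m, R)
    B = np.concatenate([np.cos(arg), np.sin(arg), np.ones((m, 1))], axis=1)
    b = rho_band[~inside]
    # least-norm solution of B c = b via the Gram matrix, with iterative
    # refinement to push the solvent residual to machine level
    gram = B @ B.T
    gram[np.diag_indices_from(gram)] += 1e-12 * np.trace(gram) / m
    lu = np.linalg.cholesky(gram)
    from scipy.linalg import cho_solve

    y = cho_solve((lu, True), b)
    for _ in range(3):
        resid = b - gram @ y
        y += cho_solve((lu, True), resid)
    c = B.T @ y
    # scatter the correction modes into Fourier coefficients:
    # a cos(2 pi h.x) + b sin(2 pi h.x)  <->  F(h) = N (a - i b) / 2
    R = len(rs)
    N = ctx.n_voxels
    F = np.zeros(grid, dtype=complex)
    coeff = 0.5 * N * (c[:R] - 1j * c[R : 2 * R])
    nx, ny, nz = grid
    hx, hy, hz = rs.hkl[:, 0] % nx, rs.hkl[:, 1] % ny, rs.hkl[:, 2] % nz
    F[hx, hy, hz] = coeff
    F[(-rs.hkl[:, 0]) % nx, (-rs.hkl[:, 1]) % ny, (-rs.hkl[:, 2]) % nz] = np.conj(
        coeff
    )
    F[0, 0, 0] = N * c[-1]
    delta = np.fft.ifftn(F).real
    return rho_band - delta


def _probe_context(cell, sg, grid) -> GridContext:
    """GridContext against an empty reflection set (grid bookkeeping only)."""
    empty = ReflectionSet(
        cell=cell,
        sg=sg,
        d_min=1e-6,
        hkl=np.zeros((0, 3), dtype=int),
        f_obs=np.zeros(0),
        sig_f=np.zeros(0),
        status=np.zeros(0, dtype=np.int8),
    )
    return GridContext(empty, grid)


def _sphere_points(
    rng: np.random.Generator, n: int, radius: float, cell: UnitCell
) -> np.ndarray:
    """n fractional offsets uniform in a sphere of given radius (Angstrom)."""
    pts = []
    lengths = np.array(cell.lengths)
    while len(pts) < n:
        p = rng.uniform(-radius, radius, size=3)
        if np.dot(p, p) <= radius * radius:
            pts.append(p / lengths)
    return np.array(pts)


def add_noise(rs: ReflectionSet, rel_sigma: float, seed: int = 0) -> ReflectionSet:
    """Perturb amplitudes with relative Gaussian noise (clipped at zero).

    Sets sigma(F) = rel_sigma * |Fobs|, so downstream flagging with the
    sigma > 2 |Fobs| rule reacts to rel_sigma > 2.
    """
    if rel_sigma < 0:
        raise ValueError("rel_sigma must be >= 0")
    out = rs.copy()
    if rel_sigma == 0:
        return out
    rng = rng_for(seed, "noise")
    noise = rng.normal(0.0, 1.0, size=len(out))
    new = np.clip(out.f_obs * (1.0 + rel_sigma * noise), 0.0, None)
    out.sig_f = rel_sigma * np.where(new > 0, new, out.f_obs)
    out.f_obs = new
    return out
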