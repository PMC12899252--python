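"""Crystallographic data model: cells, space groups, reflections, grids.

Everything downstream (projectors, iterators, the genetic scheme) works on a
full unit-cell voxel grid in P1; space-group symmetry is enforced by averaging
the density over the symmetry operations after every real-space projection,
which is numerically equivalent to iterating in the asymmetric unit but keeps
the Fourier bookkeeping exact.

Conventions
-----------
* Fractional coordinates; a voxel ``(i, j, k)`` of an ``(nx, ny, nz)`` grid
  sits at ``(i/nx, j/ny, k/nz)``.
* Structure factors are plain DFT coefficients of the voxel density,
  ``F(h) = sum_x rho(x) exp(-2 pi i h.x)``, so a real density gives Friedel
  pairs ``F(-h) = conj F(h)``.
* Phases are reported in degrees in ``[0, 360)``.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import scipy.fft as _fft

__all__ = [
    "Status",
    "UnitCell",
    "SpaceGroupInfo",
    "ReflectionSet",
    "DensityMap",
    "Mask",
    "ComplexSF",
    "PhasingConfig",
    "MetricsTrace",
    "GridContext",
    "reduce_to_asu",
    "read_reflections",
    "write_reflections",
    "assign_flags",
    "fft_density_to_sf",
    "sf_to_density",
    "choose_grid",
    "rng_for",
    "write_ccp4_map",
]


class Status(enum.IntEnum):
    """Reflection status flags (mutually exclusive)."""

    WORK = 0
    FREE = 1
    MISSING = 2
    LARGE_ERROR = 3
    LOW_RES = 4


# --------------------------------------------------------------------------
# unit cell
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class UnitCell:
    """Unit-cell lengths (Angstrom) and angles (degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180)")
        if self.volume <= 0:
            raise ValueError("cell volume must be positive")

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return self.a * self.b * self.c * math.sqrt(arg)

    def metric(self) -> np.ndarray:
        """Direct-space metric tensor G (Angstrom^2)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def reciprocal_metric(self) -> np.ndarray:
        """Reciprocal metric tensor G* so that s^2 = h G* h^T (Angstrom^-2)."""
        return np.linalg.inv(self.metric())

    def s(self, hkl: np.ndarray) -> np.ndarray:
        """Reciprocal magnitude |h*| = 1/d for integer Miller triples."""
        h = np.atleast_2d(np.asarray(hkl, dtype=float))
        gstar = self.reciprocal_metric()
        s2 = np.einsum("ni,ij,nj->n", h, gstar, h)
        return np.sqrt(np.maximum(s2, 0.0))

    def d(self, hkl: np.ndarray) -> np.ndarray:
        s = self.s(hkl)
        with np.errstate(divide="ignore"):
            return np.where(s > 0, 1.0 / np.where(s > 0, s, 1.0), np.inf)

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


# --------------------------------------------------------------------------
# space group
# --------------------------------------------------------------------------

_SHIFT_CANDIDATES = (0.0, 0.25, 1.0 / 3.0, 0.5, 2.0 / 3.0, 0.75)


@dataclasses.dataclass(frozen=True)
class SpaceGroupInfo:
    """Symmetry operations and origin bookkeeping for one space group.

    ``symops`` are pairs ``(R, t)`` acting on fractional coordinates as
    ``x -> R x + t``.  ``allowed_origin_shifts`` lists the discrete fractional
    translations that leave the symmetry description invariant;
    ``polar_axes`` marks axes along which *any* shift is allowed (floating
    origin), e.g. all three axes in P1.
    """

    symbol: str
    symops: tuple[tuple[np.ndarray, np.ndarray], ...]
    allowed_origin_shifts: tuple[tuple[float, float, float], ...]
    polar_axes: tuple[bool, bool, bool]
    has_inversion_ambiguity: bool

    @classmethod
    def from_symbol(cls, symbol: str) -> "SpaceGroupInfo":
        sg = gemmi.find_spacegroup_by_name(symbol)
        if sg is None:
            raise ValueError(f"unknown space group symbol: {symbol!r}")
        ops = []
        for op in sg.operations():
            rot = np.array(op.rot, dtype=float) / op.DEN
            tran = np.array(op.tran, dtype=float) / op.DEN
            if not np.allclose(rot, np.round(rot)):
                raise ValueError(f"non-integer rotation in {symbol}")
            ops.append((np.round(rot).astype(int), tran % 1.0))
        rots = [r for r, _ in ops]
        centro = any(np.array_equal(r, -np.eye(3, dtype=int)) for r in rots)
        polar = tuple(
            bool(all(np.array_equal(r @ e, e) for r in rots))
            for e in np.eye(3, dtype=int)
        )
        shifts = _allowed_shifts(rots, polar)
        return cls(
            symbol=sg.hm,
            symops=tuple(ops),
            allowed_origin_shifts=shifts,
            polar_axes=polar,
            has_inversion_ambiguity=not centro,
        )

    @property
    def n_ops(self) -> int:
        return len(self.symops)

    def centric(self, hkl: np.ndarray) -> np.ndarray:
        """True where the reflection's phase is symmetry-restricted."""
        h = np.atleast_2d(np.asarray(hkl, dtype=int))
        out = np.zeros(len(h), dtype=bool)
        for rot, _ in self.symops:
            out |= np.all(h @ rot == -h, axis=1)
        return out


def _allowed_shifts(
    rots: Sequence[np.ndarray], polar: tuple[bool, bool, bool]
) -> tuple[tuple[float, float, float], ...]:
    """Solve (R - I) t = 0 (mod 1) over a discrete candidate set.

    Polar axes carry a continuous family of shifts and are fixed at 0 here;
    callers combine the discrete list with free translations along them.
    """
    eye = np.eye(3, dtype=int)
    axis_cands = [
        (0.0,) if polar[k] else _SHIFT_CANDIDATES for k in range(3)
    ]
    shifts = []
    for tx in axis_cands[0]:
        for ty in axis_cands[1]:
            for tz in axis_cands[2]:
                t = np.array([tx, ty, tz])
                ok = all(
                    np.allclose(((rot - eye) @ t) % 1.0, 0.0, atol=1e-9)
                    or np.allclose(((rot - eye) @ t) % 1.0, 1.0, atol=1e-9)
                    for rot in rots
                )
                if ok:
                    shifts.append((tx, ty, tz))
    return tuple(shifts)


def reduce_to_asu(hkl: np.ndarray, sg: SpaceGroupInfo) -> np.ndarray:
    """Canonical representative of each reflection's symmetry orbit.

    The orbit includes Friedel mates; the representative is the
    lexicographically largest (h, k, l) triple, which makes uniqueness checks
    and grid lookups deterministic.
    """
    h = np.atleast_2d(np.asarray(hkl, dtype=int))
    best = h.copy()
    candidates = []
    for rot, _ in sg.symops:
        m = h @ rot
        candidates.append(m)
        candidates.append(-m)
    for c in candidates:
        better = (c[:, 0] > best[:, 0]) | (
            (c[:, 0] == best[:, 0])
            & (
                (c[:, 1] > best[:, 1])
                | ((c[:, 1] == best[:, 1]) & (c[:, 2] > best[:, 2]))
            )
        )
        best = np.where(better[:, None], c, best)
    return best


# --------------------------------------------------------------------------
# reflection data
# --------------------------------------------------------------------------


@dataclasses.dataclass
class ReflectionSet:
    """Symmetry-unique reflections with observed amplitudes and flags."""

    cell: UnitCell
    sg: SpaceGroupInfo
    d_min: float
    hkl: np.ndarray  # (n, 3) int, unique ASU representatives
    f_obs: np.ndarray  # (n,) float >= 0
    sig_f: np.ndarray  # (n,) float >= 0
    status: np.ndarray  # (n,) int8 of Status codes

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        n = len(self.hkl)
        self.f_obs = np.asarray(self.f_obs, dtype=float).reshape(n)
        self.sig_f = np.asarray(self.sig_f, dtype=float).reshape(n)
        self.status = np.asarray(self.status, dtype=np.int8).reshape(n)
        if np.any(self.f_obs < 0):
            raise ValueError("observed amplitudes must be >= 0")
        red = reduce_to_asu(self.hkl, self.sg)
        if not np.array_equal(red, self.hkl):
            bad = np.nonzero(np.any(red != self.hkl, axis=1))[0][0]
            raise ValueError(
                f"reflection {tuple(self.hkl[bad])} is not an ASU representative"
            )
        keys = {tuple(h) for h in self.hkl}
        if len(keys) != n:
            seen: dict[tuple, int] = {}
            for i, h in enumerate(map(tuple, self.hkl)):
                if h in seen:
                    raise ValueError(
                        f"duplicate reflection after reduction: {h} "
                        f"(rows {seen[h]} and {i})"
                    )
                seen[h] = i

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def s(self) -> np.ndarray:
        return self.cell.s(self.hkl)

    @property
    def d(self) -> np.ndarray:
        return self.cell.d(self.hkl)

    @property
    def work(self) -> np.ndarray:
        return self.status == Status.WORK

    @property
    def free(self) -> np.ndarray:
        return self.status == Status.FREE

    def copy(self) -> "ReflectionSet":
        return ReflectionSet(
            cell=self.cell,
            sg=self.sg,
            d_min=self.d_min,
            hkl=self.hkl.copy(),
            f_obs=self.f_obs.copy(),
            sig_f=self.sig_f.copy(),
            status=self.status.copy(),
        )


@dataclasses.dataclass
class DensityMap:
    """Real-valued voxel grid over the full unit cell."""

    values: np.ndarray
    cell: UnitCell

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("density grid must be 3-dimensional")

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy(self) -> "DensityMap":
        return DensityMap(self.values.copy(), self.cell)


@dataclasses.dataclass
class Mask:
    """Boolean protein region on a density grid."""

    inside: np.ndarray
    cell: UnitCell

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.inside.shape  # type: ignore[return-value]

    @property
    def protein_fraction(self) -> float:
        return float(self.inside.mean())


@dataclasses.dataclass
class ComplexSF:
    """Per-reflection complex structure factors aligned with a ReflectionSet."""

    hkl: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.f = np.asarray(self.f, dtype=complex).reshape(len(self.hkl))

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.f)

    @property
    def phase_deg(self) -> np.ndarray:
        return np.degrees(np.angle(self.f)) % 360.0


@dataclasses.dataclass
class PhasingConfig:
    """All knobs of one phasing run.

    The relaxation factor ``beta`` and negative-feedback factor ``gamma``
    apply to the parameterised update rules (hdm_f2/f4/f6, HIO's gamma,
    DiffMap's beta0); recommended range 0.5-1.0.
    """

    algorithm: str = "hdm_f1"  # diffmap | hio | hdm_f1 .. hdm_f6
    scheme: str = "conventional"  # conventional | res_weighted | genetic
    n_iter: int = 2000
    n_finish: int = 200
    beta0: float = 1.0
    beta: float = 0.75
    gamma: float = 0.75
    solvent_fraction: float = 0.7
    grid_spacing: float | None = None  # default d_min / 3
    seed: int = 0
    # finishing: relaxation/feedback ramp to zero over finish_ramp
    # iterations, then plain solvent flattening + amplitude projection
    finish_ramp: int = 50
    # envelope schedule
    sigma_start: float = 4.0
    sigma_end: float = 2.5
    envelope_interval: int = 10
    # resolution-weighted scheme schedule
    sigma_w_start: float = 0.8
    n_ramp: int = 600
    # flag assignment (applied by the CLI, not by run_phasing)
    free_frac: float = 0.01
    sig_ratio: float = 2.0
    d_low_cut: float = 15.0
    # convergence verdict
    r_free_threshold: float = 0.35
    r_free_window: int = 200
    dev_window: int = 1000
    # phase-error trace cadence
    phase_interval: int = 10
    # genetic scheme
    population: int = 100
    cadence: int = 100
    init_iters: int = 100
    elite: int = 5
    mutation_rate: float = 0.01
    crossover_segments: int = 5
    crossover_fraction: float = 0.5
    similarity_threshold: float = 0.98
    similarity_penalty: float = 0.5
    n_jobs: int = 1

    def __post_init__(self) -> None:
        valid = {"diffmap", "hio"} | {f"hdm_f{i}" for i in range(1, 7)}
        if self.algorithm not in valid:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.scheme not in {"conventional", "res_weighted", "genetic"}:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not 0.0 < self.solvent_fraction < 1.0:
            raise ValueError("solvent_fraction must lie in (0, 1)")
        if self.n_finish >= self.n_iter and self.n_iter > 0 and self.n_finish != self.n_iter:
            raise ValueError("n_finish must not exceed n_iter")
        if self.n_finish > self.n_iter:
            raise ValueError("n_finish must not exceed n_iter")


_TRACE_FIELDS = (
    "r_work",
    "r_free",
    "phase_error",
    "iou",
    "dev_protein",
    "dev_solvent",
)


class MetricsTrace:
    """Per-iteration convergence metrics of one run.

    ``phase_error`` and ``iou`` are NaN where a reference was unavailable or
    the metric was not evaluated at that iteration.
    """

    def __init__(self, n_iter: int = 0) -> None:
        self.n = 0
        self._data = {k: np.full(max(n_iter, 1), np.nan) for k in _TRACE_FIELDS}

    def append(self, **kwargs: float) -> None:
        if self.n >= len(self._data["r_work"]):
            for k in _TRACE_FIELDS:
                self._data[k] = np.concatenate(
                    [self._data[k], np.full(max(self.n, 1), np.nan)]
                )
        for k in _TRACE_FIELDS:
            self._data[k][self.n] = kwargs.get(k, np.nan)
        self.n += 1

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, key: str) -> np.ndarray:
        return self._data[key][: self.n]

    def last(self, key: str) -> float:
        col = self[key]
        valid = col[~np.isnan(col)]
        return float(valid[-1]) if len(valid) else float("nan")

    def to_dataframe(self):
        import pandas as pd

        d = {"iter": np.arange(self.n)}
        d.update({k: self[k] for k in _TRACE_FIELDS})
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6g")


# --------------------------------------------------------------------------
# seeded randomness
# --------------------------------------------------------------------------

_PURPOSES = {
    "init": 1,
    "flags": 2,
    "noise": 3,
    "toy": 4,
    "ga": 5,
    "mutation": 6,
    "crossover": 7,
    "selection": 8,
}


def rng_for(seed: int, purpose: str, trial: int = 0) -> np.random.Generator:
    """Counter-based stream splitting: one master seed, independent streams
    per (purpose, trial).  Reproducible regardless of evaluation order."""
    code = _PURPOSES.get(purpose)
    if code is None:
        raise ValueError(f"unknown RNG purpose {purpose!r}")
    ss = np.random.SeedSequence([int(seed) % (2**31), code, int(trial)])
    return np.random.default_rng(ss)


# --------------------------------------------------------------------------
# grid selection & context
# --------------------------------------------------------------------------


def _smooth_even(n: int) -> int:
    """Smallest even 2,3,5-smooth integer >= n (FFT friendly)."""
    m = max(int(n), 2)
    while True:
        if m % 2 == 0:
            k = m
            for p in (2, 3, 5):
                while k % p == 0:
                    k //= p
            if k == 1:
                return m
        m += 1


def choose_grid(
    cell: UnitCell,
    sg: SpaceGroupInfo,
    spacing: float,
    d_min: float | None = None,
) -> tuple[int, int, int]:
    """Pick grid dimensions compatible with spacing, Nyquist and symmetry."""
    if d_min is not None and spacing > d_min / 2.0 + 1e-9:
        raise ValueError(
            f"grid spacing {spacing:.3g} A too coarse for d_min {d_min:.3g} A "
            "(need spacing <= d_min/2)"
        )
    dims = []
    for length in cell.lengths:
        n = _smooth_even(math.ceil(length / spacing))
        dims.append(n)
    # symmetry translations must land on voxel centers; translations come
    # from the operator table in 24ths, so use that resolution
    for axis in range(3):
        for _, tran in sg.symops:
            frac = tran[axis] % 1.0
            if frac > 1e-9:
                den = round(24 / math.gcd(round(frac * 24), 24))
                while dims[axis] % den:
                    dims[axis] = _smooth_even(dims[axis] + 1)
    # ops mixing axes require equal dims on the mixed axes
    mixes = np.zeros((3, 3), dtype=bool)
    for rot, _ in sg.symops:
        mixes |= rot != 0
    for a in range(3):
        for b in range(3):
            if a != b and (mixes[a, b] or mixes[b, a]) and dims[a] != dims[b]:
                m = _smooth_even(max(dims[a], dims[b]))
                dims[a] = dims[b] = m
    return tuple(dims)  # type: ignore[return-value]


class GridContext:
    """Precomputed mapping between a reflection set and an FFT grid.

    Shared by the projectors, the iterators and the metrics so that all eight
    update rules run through a single pair of PA/PB implementations.
    """

    def __init__(self, rs: ReflectionSet, grid: tuple[int, int, int]):
        self.rs = rs
        self.grid = tuple(int(g) for g in grid)
        self.cell = rs.cell
        self.sg = rs.sg
        nx, ny, nz = self.grid
        self.n_voxels = nx * ny * nz

        hs = [np.fft.fftfreq(n, 1.0 / n).astype(int) for n in self.grid]
        hh, kk, ll = np.meshgrid(hs[0], hs[1], hs[2], indexing="ij")
        self.grid_hkl = np.stack(
            [hh.ravel(), kk.ravel(), ll.ravel()], axis=1
        )  # (N, 3)
        gstar = self.cell.reciprocal_metric()
        hf = self.grid_hkl.astype(float)
        self.grid_s2 = np.einsum("ni,ij,nj->n", hf, gstar, hf)

        # check all reflections are strictly below Nyquist on this grid
        lim = np.array([nx, ny, nz]) // 2
        if np.any(np.abs(rs.hkl) >= lim[None, :]):
            raise ValueError("grid too coarse: reflections at/beyond Nyquist")

        # map every grid coefficient to its unique reflection id (or -1)
        canon = reduce_to_asu(self.grid_hkl, self.sg)
        key = self._key(canon)
        lut = {k: i for i, k in enumerate(self._key(rs.hkl))}
        self.coeff_refl_id = np.fromiter(
            (lut.get(k, -1) for k in key), dtype=np.int64, count=self.n_voxels
        )
        # representative coefficient index per reflection
        self.repr_index = np.empty(len(rs), dtype=np.int64)
        idx_of = {k: i for i, k in enumerate(self._key(self.grid_hkl))}
        for i, k in enumerate(self._key(rs.hkl)):
            if k not in idx_of:
                raise ValueError("reflection not representable on grid")
            self.repr_index[i] = idx_of[k]

        # symmetry permutations for real-space symmetrization
        self._perms = self._build_perms()

        # half-spectrum (rfft) bookkeeping for the hot paths
        nzh = nz // 2 + 1
        self.half_shape = (nx, ny, nzh)
        hh2, kk2, ll2 = np.meshgrid(
            hs[0], hs[1], np.arange(nzh), indexing="ij"
        )
        half_hkl = np.stack([hh2.ravel(), kk2.ravel(), ll2.ravel()], axis=1)
        hf2 = half_hkl.astype(float)
        self.half_s2 = np.einsum("ni,ij,nj->n", hf2, gstar, hf2)
        canon2 = reduce_to_asu(half_hkl, self.sg)
        key2 = self._key(canon2)
        self.half_coeff_refl_id = np.fromiter(
            (lut.get(k, -1) for k in key2), dtype=np.int64, count=len(half_hkl)
        )
        # representative of each reflection within the half spectrum:
        # (h,k,l) itself if l >= 0, else the Friedel mate (-h,-k,-l) conjugated
        neg = rs.hkl[:, 2] < 0
        rep = np.where(neg[:, None], -rs.hkl, rs.hkl)
        self.half_repr_conj = neg
        self.half_repr_index = (rep[:, 0] % nx) * ny * nzh + (
            rep[:, 1] % ny
        ) * nzh + rep[:, 2]

    def _key(self, hkl: np.ndarray) -> np.ndarray:
        h = np.asarray(hkl, dtype=np.int64)
        base = 4096
        return (h[:, 0] + 2048) * base * base + (h[:, 1] + 2048) * base + (
            h[:, 2] + 2048
        )

    def _build_perms(self) -> list[np.ndarray]:
        nx, ny, nz = self.grid
        n = np.array(self.grid)
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=0)  # (3, N)
        perms = []
        for rot, tran in self.sg.symops:
            shift = tran * n
            if not np.allclose(shift, np.round(shift), atol=1e-6):
                raise ValueError(
                    "grid does not admit the space-group translations exactly"
                )
            # also require the rotation to permute voxel centers
            scaled = rot * (n[:, None] / n[None, :])
            if not np.allclose(scaled, np.round(scaled), atol=1e-9):
                raise ValueError("grid does not admit the space-group rotations")
            new = (np.round(scaled).astype(np.int64) @ idx) + np.round(shift).astype(
                np.int64
            )[:, None]
            new %= n[:, None]
            flat = (new[0] * ny + new[1]) * nz + new[2]
            perms.append(flat)
        return perms

    # -- real space <-> reciprocal space ---------------------------------

    def sf_grid(self, values: np.ndarray) -> np.ndarray:
        """Full-grid DFT coefficients of a density grid."""
        return np.fft.fftn(values)

    def density_grid(self, F: np.ndarray) -> np.ndarray:
        return np.fft.ifftn(F).real

    def gather(self, F: np.ndarray) -> np.ndarray:
        """Per-reflection complex F at the ASU representatives."""
        return F.ravel()[self.repr_index]

    # half-spectrum variants (real FFT; the iteration hot path)

    def rsf_grid(self, values: np.ndarray) -> np.ndarray:
        return _fft.rfftn(values)

    def rdensity_grid(self, F_half: np.ndarray) -> np.ndarray:
        return _fft.irfftn(F_half, self.grid)

    def rgather(self, F_half: np.ndarray) -> np.ndarray:
        f = F_half.ravel()[self.half_repr_index]
        return np.where(self.half_repr_conj, np.conj(f), f)

    def expand(self, f: np.ndarray) -> np.ndarray:
        """Scatter per-reflection complex values onto the full grid.

        Applies the symmetry phase rule F(R^T h) = exp(2 pi i h.t) F(h) and
        Friedel conjugation; coefficients not covered stay zero.
        """
        nx, ny, nz = self.grid
        out = np.zeros(self.n_voxels, dtype=complex)
        n = np.array(self.grid)
        hkl = self.rs.hkl
        for rot, tran in self.sg.symops:
            h2 = hkl @ rot  # row-vector action: h' = h R  (= R^T h)
            phase = np.exp(2j * np.pi * (hkl @ tran))
            vals = f * phase
            for hh, vv in ((h2, vals), (-h2, np.conj(vals))):
                flat = (
                    (hh[:, 0] % nx) * ny + (hh[:, 1] % ny)
                ) * nz + hh[:, 2] % nz
                out[flat] = vv
        return out.reshape(self.grid)

    def symmetrize(self, values: np.ndarray) -> np.ndarray:
        """Average a density grid over the space-group operations."""
        if len(self._perms) == 1:
            return values
        flat = values.ravel()
        acc = np.zeros_like(flat)
        for perm in self._perms:
            acc += flat[perm]
        return (acc / len(self._perms)).reshape(values.shape)


def _context_for(map_or_grid, rs: ReflectionSet) -> GridContext:
    grid = map_or_grid.grid if isinstance(map_or_grid, DensityMap) else tuple(map_or_grid)
    return GridContext(rs, grid)


def fft_density_to_sf(
    dmap: DensityMap, rs: ReflectionSet, ctx: GridContext | None = None
) -> ComplexSF:
    """Structure factors of a density map at the unique reflections."""
    ctx = ctx or _context_for(dmap, rs)
    F = ctx.sf_grid(dmap.values)
    return ComplexSF(rs.hkl, ctx.gather(F))


def sf_to_density(
    sf: ComplexSF,
    rs: ReflectionSet,
    grid: tuple[int, int, int],
    ctx: GridContext | None = None,
) -> DensityMap:
    """Synthesize the band-limited density from unique-reflection coefficients."""
    ctx = ctx or GridContext(rs, grid)
    F = ctx.expand(sf.f)
    return DensityMap(ctx.density_grid(F), rs.cell)


# --------------------------------------------------------------------------
# flags
# --------------------------------------------------------------------------


def assign_flags(
    rs: ReflectionSet,
    free_frac: float = 0.01,
    sig_ratio: float = 2.0,
    d_low_cut: float = 15.0,
    seed: int = 0,
) -> ReflectionSet:
    """Assign status flags: large-error > low-resolution > free > work.

    ``free_frac`` of the remaining work reflections are flagged free (seeded,
    reproducible); reflections with sigma > sig_ratio * |Fobs| are flagged as
    large-error and those with d > d_low_cut as low-resolution.  Flagged
    reflections are excluded from the amplitude constraint and filled from
    calculated values during projection.
    """
    if not 0.0 <= free_frac < 1.0:
        raise ValueError("free_frac must lie in [0, 1)")
    out = rs.copy()
    n = len(out)
    status = np.full(n, Status.WORK, dtype=np.int8)
    large = out.sig_f > sig_ratio * out.f_obs
    low = out.d > d_low_cut
    status[low] = Status.LOW_RES
    status[large] = Status.LARGE_ERROR
    eligible = np.nonzero(status == Status.WORK)[0]
    n_free = round(len(out) * free_frac)
    if n_free > 0 and len(eligible):
        rng = rng_for(seed, "flags")
        pick = rng.choice(eligible, size=min(n_free, len(eligible)), replace=False)
        status[pick] = Status.FREE
    out.status = status
    return out


# --------------------------------------------------------------------------
# reflection I/O
# --------------------------------------------------------------------------

_STATUS_NAMES = {s.name.lower(): s for s in Status}


def read_reflections(path, dialect: str | None = None) -> ReflectionSet:
    """Read a reflection file (plain-text dialect or MTZ).

    Text dialect: header lines ``CELL a b c alpha beta gamma``,
    ``SPACEGROUP symbol``, ``DMIN value``; then whitespace-separated rows
    ``h k l Fobs sigF [status]``.
    """
    path = Path(path)
    if dialect is None:
        dialect = "mtz" if path.suffix.lower() == ".mtz" else "text"
    if dialect == "mtz":
        return _read_mtz(path)
    if dialect != "text":
        raise ValueError(f"unknown dialect {dialect!r}")
    cell = sg = None
    d_min = None
    rows = []
    statuses = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        key = parts[0].upper()
        if key == "CELL":
            cell = UnitCell(*(float(x) for x in parts[1:7]))
        elif key == "SPACEGROUP":
            sg = SpaceGroupInfo.from_symbol(" ".join(parts[1:]))
        elif key == "DMIN":
            d_min = float(parts[1])
        else:
            h, k, l = (int(x) for x in parts[:3])
            fobs, sigf = float(parts[3]), float(parts[4])
            st = _STATUS_NAMES[parts[5].lower()] if len(parts) > 5 else Status.WORK
            rows.append((h, k, l, fobs, sigf))
            statuses.append(st)
    if cell is None or sg is None:
        raise ValueError(f"{path}: missing CELL or SPACEGROUP header")
    hkl = np.array([(r[0], r[1], r[2]) for r in rows], dtype=int)
    red = reduce_to_asu(hkl, sg)
    if not np.array_equal(red, hkl):
        i = int(np.nonzero(np.any(red != hkl, axis=1))[0][0])
        raise ValueError(
            f"{path}: reflection {tuple(hkl[i])} reduces to {tuple(red[i])}"
        )
    f_obs = np.array([r[3] for r in rows])
    sig_f = np.array([r[4] for r in rows])
    if d_min is None:
        d_min = float(cell.d(hkl).min())
    return ReflectionSet(
        cell=cell,
        sg=sg,
        d_min=d_min,
        hkl=hkl,
        f_obs=f_obs,
        sig_f=sig_f,
        status=np.array(statuses, dtype=np.int8),
    )


def write_reflections(
    path, rs: ReflectionSet, phases: ComplexSF | None = None, dialect: str | None = None
) -> None:
    """Write a reflection set (text dialect or MTZ, chosen by extension)."""
    path = Path(path)
    if dialect is None:
        dialect = "mtz" if path.suffix.lower() == ".mtz" else "text"
    if dialect == "mtz":
        _write_mtz(path, rs, phases)
        return
    lines = [
        "# hdmphase reflection file",
        f"CELL {rs.cell.a:.6g} {rs.cell.b:.6g} {rs.cell.c:.6g} "
        f"{rs.cell.alpha:.6g} {rs.cell.beta:.6g} {rs.cell.gamma:.6g}",
        f"SPACEGROUP {rs.sg.symbol}",
        f"DMIN {rs.d_min:.6g}",
    ]
    phis = phases.phase_deg if phases is not None else None
    for i in range(len(rs)):
        h, k, l = rs.hkl[i]
        row = (
            f"{h} {k} {l} {float(rs.f_obs[i])!r} {float(rs.sig_f[i])!r} "
            f"{Status(rs.status[i]).name.lower()}"
        )
        if phis is not None:
            row += f" {phis[i]:.4f}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def _read_mtz(path) -> ReflectionSet:
    mtz = gemmi.read_mtz_file(str(path))
    cell = UnitCell(
        mtz.cell.a, mtz.cell.b, mtz.cell.c, mtz.cell.alpha, mtz.cell.beta, mtz.cell.gamma
    )
    sg = SpaceGroupInfo.from_symbol(mtz.spacegroup.hm)
    labels = [c.label for c in mtz.columns]
    data = np.array(mtz, copy=True)

    def col(name):
        return data[:, labels.index(name)]

    hkl = np.stack([col("H"), col("K"), col("L")], axis=1).astype(int)
    hkl = reduce_to_asu(hkl, sg)
    f_obs = col("F")
    sig_f = col("SIGF") if "SIGF" in labels else np.zeros(len(f_obs))
    status = np.full(len(f_obs), Status.WORK, dtype=np.int8)
    if "FreeR_flag" in labels:
        status[col("FreeR_flag").astype(int) == 0] = Status.FREE
    rs = ReflectionSet(
        cell=cell,
        sg=sg,
        d_min=float(cell.d(hkl).min()),
        hkl=hkl,
        f_obs=f_obs,
        sig_f=sig_f,
        status=status,
    )
    return rs


def _write_mtz(path, rs: ReflectionSet, phases: ComplexSF | None = None) -> None:
    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = gemmi.find_spacegroup_by_name(rs.sg.symbol)
    mtz.set_cell_for_all(rs.cell.to_gemmi())
    mtz.add_dataset("hdmphase")
    mtz.add_column("F", "F")
    mtz.add_column("SIGF", "Q")
    mtz.add_column("FreeR_flag", "I")
    cols = [
        rs.hkl[:, 0],
        rs.hkl[:, 1],
        rs.hkl[:, 2],
        rs.f_obs,
        rs.sig_f,
        np.where(rs.status == Status.FREE, 0, 1),
    ]
    if phases is not None:
        mtz.add_column("PHIC", "P")
        cols.append(phases.phase_deg)
    mtz.set_data(np.stack([np.asarray(c, dtype=float) for c in cols], axis=1))
    mtz.write_to_file(str(path))


def write_ccp4_map(path, dmap: DensityMap, sg: SpaceGroupInfo | None = None) -> None:
    """Write a density (or 0/1 mask) grid as a CCP4/MRC map."""
    grid = gemmi.FloatGrid(np.asarray(dmap.values, dtype=np.float32))
    grid.set_unit_cell(dmap.cell.to_gemmi())
    if sg is not None:
        grid.spacegroup = gemmi.find_spacegroup_by_name(sg.symbol)
    else:
        grid.spacegroup = gemmi.find_spacegroup_by_name("P 1")
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))
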