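"""Alignment and ensemble averaging of independently converged maps.

Independently converged phasing solutions differ by an allowed origin shift
and, in non-centrosymmetric space groups, possibly by an inversion.  After
aligning every map to a common reference (the lowest-Rfree map when scores
are supplied, otherwise the first), the voxel-wise mean suppresses the
independent random error of the individual solutions, which consistently
lowers the mean phase error relative to the individual maps.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as _fft

from . import _align
from .core import ComplexSF, DensityMap, GridContext, ReflectionSet, SpaceGroupInfo
from .projections import project_fourier_grid

__all__ = ["align_pair", "average_maps", "phases_of_average"]


def align_pair(
    ref: DensityMap, mov: DensityMap, sg: SpaceGroupInfo
) -> DensityMap:
    """Transform ``mov`` over allowed origin shifts (and inversion, when the
    space group is non-centrosymmetric) to maximize real-space correlation
    with ``ref``.  The correlation is never decreased: the identity transform
    is part of the searched set."""
    if ref.grid != mov.grid:
        raise ValueError("maps live on different grids")
    F_ref = _fft.rfftn(ref.values)
    F_mov = _fft.rfftn(mov.values)
    al = _align.best_alignment(F_ref, F_mov, sg, ref.grid)
    return DensityMap(_align.apply_alignment_grid(mov.values, al), mov.cell)


def average_maps(
    maps: list[DensityMap],
    sg: SpaceGroupInfo,
    scores: list[float] | None = None,
    max_maps: int = 20,
) -> DensityMap:
    """Align all maps to a reference and return the voxel-wise mean.

    ``scores`` (e.g. per-map Rfree, lower is better) selects the reference
    and the order in which maps enter the average; at most ``max_maps`` are
    used, since the improvement from averaging saturates around 20 solutions.
    Averaging a single map returns it unchanged.
    """
    if not maps:
        raise ValueError("need at least one map")
    order = np.argsort(scores) if scores is not None else np.arange(len(maps))
    order = order[: max_maps if max_maps else len(maps)]
    ref = maps[int(order[0])]
    acc = ref.values.astype(float).copy()
    for i in order[1:]:
        acc += align_pair(ref, maps[int(i)], sg).values
    return DensityMap(acc / len(order), ref.cell)


def phases_of_average(
    avg: DensityMap, rs: ReflectionSet, ctx: GridContext | None = None
) -> ComplexSF:
    """Final phase set of an averaged map, after one amplitude projection.

    Re-projecting through PB restores the observed amplitudes (averaging
    shrinks them where the ensemble disagrees) and emits the phases."""
    ctx = ctx or GridContext(rs, avg.grid)
    values, _ = project_fourier_grid(avg.values, ctx)
    F = ctx.sf_grid(values)
    return ComplexSF(rs.hkl, ctx.gather(F))
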