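"""Population-based genetic evolution layered over any iterative rule.

A population of independent phasing trials advances in lockstep; every
``cadence`` iterations the population exchanges information through genetic
operations: fitness evaluation from Rwork with a dynamic threshold,
roulette-wheel parent selection with a similarity penalty against premature
convergence, multi-segment crossover of density values, 1% mutation, and
elitism.  Before crossover all maps are aligned (allowed origin shifts +
enantiomer) to the fittest individual so that exchanged density segments are
spatially meaningful.  Once every individual satisfies the internal
convergence criterion the evolution terminates early and each individual
concludes with the solvent-flattening finishing protocol.
"""

from __future__ import annotations

import dataclasses
from concurrent.futures import ProcessPoolExecutor

import numpy as np
import scipy.fft as _fft

from . import _align
from .core import (
    ComplexSF,
    DensityMap,
    GridContext,
    Mask,
    PhasingConfig,
    ReflectionSet,
    SpaceGroupInfo,
    rng_for,
)
from .envelope import gaussian_weights_grid, mask_from_weights_grid
from .iterators import PhasingEngine, PhasingResult
from .projections import HistogramRef

__all__ = [
    "Individual",
    "Population",
    "fitness",
    "select_parent",
    "crossover",
    "mutate",
    "align_to_fittest",
    "evolve",
    "run_genetic",
    "GeneticResult",
]


@dataclasses.dataclass
class Individual:
    """One GA chromosome: density values on the chromosome grid."""

    chrom: DensityMap
    r_work: float
    fitness: float = 0.0
    converged: bool = False

    def copy(self) -> "Individual":
        return Individual(self.chrom.copy(), self.r_work, self.fitness, self.converged)


@dataclasses.dataclass
class Population:
    individuals: list[Individual]
    generation: int = 0

    @property
    def r_values(self) -> np.ndarray:
        return np.array([ind.r_work for ind in self.individuals])

    @property
    def r_avg(self) -> float:
        return float(self.r_values.mean())

    @property
    def r_min(self) -> float:
        return float(self.r_values.min())

    @property
    def r_thres(self) -> float:
        return self.r_avg + (self.r_avg - self.r_min)

    @property
    def fittest(self) -> Individual:
        return self.individuals[int(np.argmin(self.r_values))]

    def __len__(self) -> int:
        return len(self.individuals)


def fitness(r_work: float, r_avg: float, r_min: float) -> float:
    """Dynamic fitness: f = (Rthres - Rwork) / (Rthres - Rmin), clamped to
    [0, 1], zero at or above Rthres = Ravg + (Ravg - Rmin).  A fully uniform
    population (Rthres == Rmin) gets fitness 1 everywhere."""
    if r_min > r_avg + 1e-12:
        raise ValueError("r_min must not exceed r_avg")
    r_thres = r_avg + (r_avg - r_min)
    if r_thres - r_min <= 1e-300:
        return 1.0
    if r_work >= r_thres:
        return 0.0
    return float(np.clip((r_thres - r_work) / (r_thres - r_min), 0.0, 1.0))


def select_parent(pop: Population, rng: np.random.Generator) -> Individual:
    """Roulette-wheel selection proportional to (penalized) fitness;
    uniform fallback when every fitness is zero."""
    f = np.array([ind.fitness for ind in pop.individuals])
    total = f.sum()
    if total <= 0:
        idx = int(rng.integers(0, len(pop)))
    else:
        idx = int(rng.choice(len(pop), p=f / total))
    return pop.individuals[idx]


def _axis_interval(n: int, start: int, length: int) -> np.ndarray:
    m = np.zeros(n, dtype=bool)
    m[(start + np.arange(length)) % n] = True
    return m


def segment_mask(
    rng: np.random.Generator,
    grid: tuple[int, int, int],
    n_segments: int = 5,
    fraction: float = 0.5,
    tol: float = 0.02,
) -> np.ndarray:
    """Union of random axis-aligned (periodically wrapped) boxes covering
    ``fraction`` of the grid to within ``tol``.

    Box anchors, aspect ratios and relative sizes are drawn once; a global
    scale factor is then bisected so the union fraction hits the target.
    """
    grid = tuple(grid)
    n_tot = int(np.prod(grid))
    starts = np.stack([rng.integers(0, n, size=n_segments) for n in grid], axis=1)
    aspects = rng.uniform(0.6, 1.6, size=(n_segments, 3))
    rel = rng.uniform(0.5, 1.5, size=n_segments)
    rel = rel / rel.sum() * fraction  # per-box volume fractions

    def union(scale: float) -> np.ndarray:
        out = np.zeros(grid, dtype=bool)
        for b in range(n_segments):
            cube = (rel[b] ** (1.0 / 3.0)) * aspects[b] * scale
            dims = [
                int(np.clip(round(cube[k] * grid[k]), 1, grid[k])) for k in range(3)
            ]
            ax = [
                _axis_interval(grid[k], int(starts[b, k]), dims[k]) for k in range(3)
            ]
            out |= (
                ax[0][:, None, None] & ax[1][None, :, None] & ax[2][None, None, :]
            )
        return out

    lo, hi = 0.2, 3.0
    best, best_err = None, np.inf
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        m = union(mid)
        frac = m.sum() / n_tot
        err = abs(frac - fraction)
        if err < best_err:
            best, best_err = m, err
        if err <= tol * 0.5:
            break
        if frac < fraction:
            lo = mid
        else:
            hi = mid
    return best


def crossover(
    a: Individual,
    b: Individual,
    rng: np.random.Generator,
    n_segments: int = 5,
    fraction: float = 0.5,
) -> tuple[Individual, Individual]:
    """Exchange density values inside ``n_segments`` random 3-D segments
    whose union covers ``fraction`` (+-2%) of the grid.  Outside the
    segments, offspring equal their parents; the exchange conserves the
    combined multiset of voxel values."""
    mask = segment_mask(rng, a.chrom.grid, n_segments, fraction)
    va, vb = a.chrom.values, b.chrom.values
    o1 = va.copy()
    o2 = vb.copy()
    o1[mask] = vb[mask]
    o2[mask] = va[mask]
    return (
        Individual(DensityMap(o1, a.chrom.cell), np.nan),
        Individual(DensityMap(o2, b.chrom.cell), np.nan),
    )


def mutate(ind: Individual, rate: float, rng: np.random.Generator) -> Individual:
    """Replace each voxel independently with Uniform[0, 1] with prob. rate."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must lie in [0, 1]")
    out = ind.chrom.values.copy()
    if rate > 0:
        hit = rng.random(out.shape) < rate
        out[hit] = rng.uniform(0.0, 1.0, size=int(hit.sum()))
    return Individual(DensityMap(out, ind.chrom.cell), np.nan, 0.0, False)


def _mask_of(values: np.ndarray, grid_s2, solvent_fraction: float, sigma: float = 2.5):
    w = gaussian_weights_grid(values, grid_s2, sigma)
    return mask_from_weights_grid(w, solvent_fraction)


def align_to_fittest(
    pop: Population,
    sg: SpaceGroupInfo,
    solvent_fraction: float,
    ctx: GridContext | None = None,
) -> Population:
    """Align every individual's density to the fittest one.

    The transform (allowed origin shift + optional inversion) maximizing the
    real-space density correlation with the fittest chromosome is applied;
    the fittest individual is left untouched and the identity transform is
    part of the search, so overlap never decreases.  Density correlation is
    used rather than mask overlap alone because a compact protein envelope is
    nearly centrosymmetric: masks cannot resolve the enantiomer hand, and
    crossover between opposite hands produces meaningless offspring.
    Maximizing density overlap subsumes maximizing mask overlap for maps of a
    common structure.
    """
    r = pop.r_values
    best_idx = int(np.argmin(r))
    fittest = pop.individuals[best_idx]
    grid = fittest.chrom.grid
    F_ref = _fft.rfftn(fittest.chrom.values)
    out = []
    for i, ind in enumerate(pop.individuals):
        if i == best_idx:
            out.append(ind)
            continue
        F_mov = _fft.rfftn(ind.chrom.values)
        al = _align.best_alignment(F_ref, F_mov, sg, grid)
        moved = _align.apply_alignment_grid(ind.chrom.values, al)
        out.append(
            Individual(DensityMap(moved, ind.chrom.cell), ind.r_work, ind.fitness, ind.converged)
        )
    return Population(out, pop.generation)


def _similarity_penalty(
    pop: Population,
    elites: set[int],
    threshold: float,
    penalty: float,
) -> None:
    """Halve (by ``penalty``) the fitness of near-duplicate individuals.

    An individual is penalized when its density correlates above
    ``threshold`` with any individual of better (lower) Rwork; elites are
    exempt."""
    r = pop.r_values
    vals = [ind.chrom.values.ravel() for ind in pop.individuals]
    centered = [v - v.mean() for v in vals]
    norms = [np.linalg.norm(v) + 1e-300 for v in centered]
    order = np.argsort(r)
    for rank, i in enumerate(order):
        if i in elites:
            continue
        for j in order[:rank]:
            c = float(np.dot(centered[i], centered[j]) / (norms[i] * norms[j]))
            if c > threshold:
                pop.individuals[i].fitness *= penalty
                break


def evolve(
    pop: Population,
    cfg: PhasingConfig,
    sg: SpaceGroupInfo,
    rng: np.random.Generator,
    ctx: GridContext | None = None,
) -> tuple[Population, bool]:
    """One generation: fitness -> penalty -> align -> elitism + offspring.

    Returns the next population (same size; elites copied bit-identically)
    and the early-termination flag (every individual converged)."""
    if all(ind.converged for ind in pop.individuals):
        return pop, True
    r_avg, r_min = pop.r_avg, pop.r_min
    for ind in pop.individuals:
        ind.fitness = fitness(ind.r_work, r_avg, r_min)
    n_elite = min(cfg.elite, len(pop))
    elite_idx = list(np.argsort(pop.r_values)[:n_elite])
    _similarity_penalty(
        pop, set(int(i) for i in elite_idx), cfg.similarity_threshold, cfg.similarity_penalty
    )
    aligned = align_to_fittest(pop, sg, cfg.solvent_fraction, ctx)
    nxt: list[Individual] = [pop.individuals[int(i)].copy() for i in elite_idx]
    while len(nxt) < len(pop):
        pa = select_parent(aligned, rng)
        pb = select_parent(aligned, rng)
        o1, o2 = crossover(
            pa, pb, rng, cfg.crossover_segments, cfg.crossover_fraction
        )
        for o in (o1, o2):
            if len(nxt) < len(pop):
                nxt.append(mutate(o, cfg.mutation_rate, rng))
    return Population(nxt, pop.generation + 1), False


# -- run driver ------------------------------------------------------------


@dataclasses.dataclass
class GeneticResult:
    """Outcome of a genetic-evolution run."""

    results: list[PhasingResult]
    early_stop: bool
    generations: int
    first_converged_generation: int | None
    all_converged_generation: int | None


def _advance_engine(args):
    engine, k = args
    engine.advance(k)
    return engine


def _advance_all(engines, k: int, n_jobs: int):
    if n_jobs <= 1:
        for e in engines:
            e.advance(k)
        return engines
    with ProcessPoolExecutor(max_workers=n_jobs) as pool:
        return list(pool.map(_advance_engine, [(e, k) for e in engines]))


def save_checkpoint(path, engines, gen: int, ages: list[int]) -> None:
    """Archive the population state (one file; per-individual map + trace)."""
    payload = {"gen": np.array([gen]), "ages": np.array(ages)}
    for i, e in enumerate(engines):
        payload[f"rho_{i}"] = e.rho
        payload[f"it_{i}"] = np.array([e.it])
        payload[f"trace_n_{i}"] = np.array([e.trace.n])
        for key in ("r_work", "r_free", "phase_error", "iou", "dev_protein", "dev_solvent"):
            payload[f"trace_{key}_{i}"] = e.trace[key]
    np.savez_compressed(path, **payload)


def load_checkpoint(path, engines, ages: list[int]) -> int:
    """Restore a population archive into freshly constructed engines.

    The envelope and cached estimate are rebuilt from the restored density
    at the next iteration; continuation is deterministic from the restored
    state (not bit-identical to an uninterrupted run, whose envelope source
    is the pre-checkpoint constrained estimate)."""
    data = np.load(path)
    for i, e in enumerate(engines):
        e.rho = data[f"rho_{i}"]
        e.it = int(data[f"it_{i}"][0])
        e.inside = None
        e._last_estimate = None
        n = int(data[f"trace_n_{i}"][0])
        e.trace.n = 0
        for t in range(n):
            e.trace.append(
                **{
                    key: data[f"trace_{key}_{i}"][t]
                    for key in (
                        "r_work", "r_free", "phase_error", "iou",
                        "dev_protein", "dev_solvent",
                    )
                }
            )
    ages[:] = list(data["ages"])
    return int(data["gen"][0])


def run_genetic(
    rs: ReflectionSet,
    href: HistogramRef,
    cfg: PhasingConfig,
    truth: ComplexSF | None = None,
    true_mask: Mask | None = None,
    ctx: GridContext | None = None,
    checkpoint: str | None = None,
    resume: str | None = None,
) -> GeneticResult:
    """Genetic-evolution phasing: one population instead of N trials.

    Each of ``cfg.population`` individuals starts from its own random
    density (streams split from cfg.seed by slot index) and first runs
    ``cfg.init_iters`` plain iterations to establish diversity.  Between
    cadence blocks the population evolves; with crossover and mutation
    disabled (rate 0, fraction 0) the scheme reduces to independent runs.
    """
    n = cfg.population
    engines = [
        PhasingEngine(rs, href, cfg, ctx=ctx, truth=truth, true_mask=true_mask, trial=i)
        for i in range(n)
    ]
    for e in engines:
        # slot trajectories are discontinuous across genetic replacements;
        # judge convergence by the sustained-Rfree clause alone
        e.conv_require_dev = False
    ctx0 = engines[0].ctx
    engines = _advance_all(engines, cfg.init_iters, cfg.n_jobs)
    n_main = cfg.n_iter - cfg.n_finish
    early = False
    gen = 0
    first_gen = None
    all_gen = None
    # a freshly inserted offspring is given a few cadence periods to lock in
    # and fire the convergence verdict before it can be replaced again
    maturity = 2
    ages = [maturity] * n
    if resume:
        gen = load_checkpoint(resume, engines, ages)
    while engines[0].it < n_main:
        block = min(cfg.cadence, n_main - engines[0].it)
        engines = _advance_all(engines, block, cfg.n_jobs)
        gen += 1
        ages = [a + 1 for a in ages]
        if checkpoint:
            save_checkpoint(checkpoint, engines, gen, ages)
        conv = [e.converged_iteration() is not None for e in engines]
        if any(conv) and first_gen is None:
            first_gen = gen
        if all(conv):
            all_gen = gen
            early = True
            break
        pop = Population(
            [
                Individual(
                    DensityMap(e.rho, rs.cell),
                    e.trace.last("r_work"),
                    converged=c,
                )
                for e, c in zip(engines, conv)
            ],
            generation=gen,
        )
        rng = rng_for(cfg.seed, "ga", gen)
        nxt, _ = evolve(pop, cfg, rs.sg, rng, ctx0)
        # elites and already-converged slots keep their engine state;
        # offspring replace the rest (so convergence flags stay truthful)
        elite_n = min(cfg.elite, n)
        elite_idx = list(int(i) for i in np.argsort(pop.r_values)[:elite_n])
        protected = (
            set(elite_idx)
            | {i for i in range(n) if conv[i]}
            | {i for i in range(n) if ages[i] < maturity}
        )
        # slots whose Rwork already sits at the converged level are locked:
        # they are awaiting their verdict window, churning them would only
        # reset the clock
        verd_rw = [pop.r_values[i] for i in range(n) if conv[i]]
        if verd_rw:
            lock = 1.2 * float(np.median(verd_rw))
            protected |= {i for i in range(n) if pop.r_values[i] < lock}
        offspring = [
            ind for k, ind in enumerate(nxt.individuals) if k >= elite_n
        ]
        oi = 0
        for i in range(n):
            if i in protected:
                continue
            if oi >= len(offspring):
                break
            engines[i].rho = offspring[oi].chrom.values
            # rebuild the envelope from the offspring itself: the cached
            # estimate belongs to the replaced density at another origin
            engines[i].inside = None
            engines[i]._last_estimate = None
            ages[i] = 0
            oi += 1
    for e in engines:
        e.run_finishing()
    results = [e.result() for e in engines]
    return GeneticResult(
        results=results,
        early_stop=early,
        generations=gen,
        first_converged_generation=first_gen,
        all_converged_generation=all_gen,
    )
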