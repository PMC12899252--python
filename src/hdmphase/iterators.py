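"""Per-iteration update rules and the phasing run loop.

Eight update rules share one pair of projector implementations (PA/PB):

========  ==========================================  ==================
rule      protein region                              solvent region
========  ==========================================  ==================
diffmap   rho + beta0 (rhoA - rhoB), two-candidate    (same, global)
hio       PA PB rho                                   rho - gamma PB rho
hdm_f1    PA PB rho + (2 PA PB - PA - PB) rho         rho - PB rho
hdm_f2    PA PB rho + beta (2 PA PB - PA - PB) rho    rho - gamma PB rho
hdm_f3    PA PB rho + (PA PB - PA) rho                rho - PB rho
hdm_f4    PA PB rho + beta (PA PB - PA) rho           rho - gamma PB rho
hdm_f5    PA PB rho + (PA PB - PB) rho                rho - PB rho
hdm_f6    PA PB rho + beta (PA PB - PB) rho           rho - gamma PB rho
========  ==========================================  ==================

At beta0 = 1 the two-candidate DiffMap update simplifies to the global form
rho + (2 PA PB - PA - PB) rho, which partitions into the hdm_f1 table row
without its leading PA PB term; the implementation uses that simplified form
at beta0 == 1 (treating the projector composition as the derivation does) so
the printed identities hold exactly.

Each step performs exactly one PB evaluation, and PA(PB rho) / PA(rho) are
each evaluated at most once and reused for the convergence metrics.

A run starts from seeded uniform random density, rebuilds the molecular
envelope on a fixed cadence, applies one update per iteration, and records
metrics.  During the final ``n_finish`` iterations the update rule is
gradually turned off -- the relaxation and feedback factors ramp linearly to
zero over the first ``finish_ramp`` iterations of the finishing phase -- and
every finishing iterate is polished by a plain PA(PB(.)) pass (solvent
flattening + amplitude projection), which is all that remains once the ramp
has completed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import metrics as _metrics
from .core import (
    ComplexSF,
    DensityMap,
    GridContext,
    Mask,
    MetricsTrace,
    PhasingConfig,
    ReflectionSet,
    choose_grid,
    rng_for,
)
from .envelope import gaussian_weights_grid, mask_from_weights_grid, sigma_schedule
from .projections import HistogramRef, project_fourier_grid, project_real_grid
from .strategies import resolution_weights, sigma_w_schedule

__all__ = [
    "IterState",
    "PhasingResult",
    "PhasingEngine",
    "step_diffmap",
    "step_hio",
    "step_hdm",
    "run_phasing",
    "convergence_iteration",
]


@dataclasses.dataclass
class IterState:
    """Current iterate: density, protein mask, iteration counter, trace."""

    rho: DensityMap
    mask: Mask
    iter: int = 0
    trace: MetricsTrace | None = None


def _pa(ctx: GridContext, values: np.ndarray, inside: np.ndarray, href: HistogramRef):
    """Real-space projection followed by symmetry averaging."""
    return ctx.symmetrize(project_real_grid(values, inside, href))


def apply_step_grid(
    algorithm: str,
    rho: np.ndarray,
    inside: np.ndarray,
    href: HistogramRef,
    ctx: GridContext,
    beta0: float = 1.0,
    beta: float = 1.0,
    gamma: float = 1.0,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """One update of any of the eight rules, on raw grids.

    Returns the next iterate and a cache with the operator evaluations
    (``rho``, ``pb``, ``papb``, optionally ``pa``), the calculated structure
    factors and the full coefficient array of the input density.
    """
    pb, pbinfo = project_fourier_grid(rho, ctx, weights)
    cache: dict = {"rho": rho, "pb": pb}
    cache.update(pbinfo)

    if algorithm == "diffmap":
        pa_rho = _pa(ctx, rho, inside, href)
        cache["pa"] = pa_rho
        papb = _pa(ctx, pb, inside, href)
        cache["papb"] = papb
        if beta0 == 1.0:
            new = rho + beta * (2.0 * papb - pa_rho - pb)
        else:
            if beta0 == 0.0:
                raise ValueError("beta0 must be nonzero")
            inv = 1.0 / beta0
            rho_a = _pa(ctx, (1.0 + inv) * pb - inv * rho, inside, href)
            rho_b, _ = project_fourier_grid(
                (1.0 - inv) * pa_rho + inv * rho, ctx, weights
            )
            new = rho + beta * beta0 * (rho_a - rho_b)
        return new, cache

    papb = _pa(ctx, pb, inside, href)
    cache["papb"] = papb
    if algorithm == "hio":
        protein = papb
    elif algorithm in ("hdm_f1", "hdm_f2"):
        pa_rho = _pa(ctx, rho, inside, href)
        cache["pa"] = pa_rho
        protein = papb + beta * (2.0 * papb - pa_rho - pb)
    elif algorithm in ("hdm_f3", "hdm_f4"):
        pa_rho = _pa(ctx, rho, inside, href)
        cache["pa"] = pa_rho
        protein = papb + beta * (papb - pa_rho)
    elif algorithm in ("hdm_f5", "hdm_f6"):
        protein = papb + beta * (papb - pb)
    else:
        raise ValueError(f"unknown formula {algorithm!r}")
    new = np.where(inside, protein, rho - gamma * pb)
    return new, cache


def _effective_params(algorithm: str, cfg_beta: float, cfg_gamma: float, ramp: float):
    """beta/gamma actually applied: the parameter-free rules f1/f3/f5 have
    beta = gamma = 1 (scaled only by the finishing ramp)."""
    if algorithm in ("hdm_f1", "hdm_f3", "hdm_f5", "diffmap"):
        return ramp, ramp
    if algorithm == "hio":
        return 1.0, cfg_gamma * ramp
    return cfg_beta * ramp, cfg_gamma * ramp


# -- public single-step operations -----------------------------------------


def _state_ctx(state: IterState, rs: ReflectionSet, ctx: GridContext | None):
    return ctx or GridContext(rs, state.rho.grid)


def step_diffmap(
    state: IterState,
    rs: ReflectionSet,
    href: HistogramRef,
    beta0: float = 1.0,
    weights: np.ndarray | None = None,
    ctx: GridContext | None = None,
) -> DensityMap:
    """Two-candidate difference-map update (global simplified form at beta0=1)."""
    ctx = _state_ctx(state, rs, ctx)
    new, _ = apply_step_grid(
        "diffmap", state.rho.values, state.mask.inside, href, ctx,
        beta0=beta0, beta=1.0, gamma=1.0, weights=weights,
    )
    return DensityMap(new, state.rho.cell)


def step_hio(
    state: IterState,
    rs: ReflectionSet,
    href: HistogramRef,
    gamma: float = 0.75,
    weights: np.ndarray | None = None,
    ctx: GridContext | None = None,
) -> DensityMap:
    """Hybrid input-output update with PA PB in the protein region."""
    ctx = _state_ctx(state, rs, ctx)
    new, _ = apply_step_grid(
        "hio", state.rho.values, state.mask.inside, href, ctx,
        beta=1.0, gamma=gamma, weights=weights,
    )
    return DensityMap(new, state.rho.cell)


def step_hdm(
    state: IterState,
    rs: ReflectionSet,
    href: HistogramRef,
    formula: str = "f1",
    beta: float = 1.0,
    gamma: float = 1.0,
    weights: np.ndarray | None = None,
    ctx: GridContext | None = None,
) -> DensityMap:
    """One hybrid difference-map update (formula 'f1' .. 'f6').

    beta and gamma are ignored for the parameter-free formulas f1/f3/f5.
    """
    name = formula if formula.startswith("hdm_") else f"hdm_{formula}"
    if name not in {f"hdm_f{i}" for i in range(1, 7)}:
        raise ValueError(f"unknown formula {formula!r}")
    ctx = _state_ctx(state, rs, ctx)
    b, g = _effective_params(name, beta, gamma, 1.0)
    new, _ = apply_step_grid(
        name, state.rho.values, state.mask.inside, href, ctx,
        beta=b, gamma=g, weights=weights,
    )
    return DensityMap(new, state.rho.cell)


# -- run loop --------------------------------------------------------------


@dataclasses.dataclass
class PhasingResult:
    """Outcome of one phasing run; unpacks as (map, phases, trace, converged)."""

    map: DensityMap
    phases: ComplexSF
    trace: MetricsTrace
    converged: bool
    failed: bool = False
    converged_at: int | None = None
    phase_error: float = float("nan")
    r_work: float = float("nan")
    r_free: float = float("nan")

    def __iter__(self):
        return iter((self.map, self.phases, self.trace, self.converged))


def convergence_iteration(
    trace: MetricsTrace,
    cfg: PhasingConfig,
    start: int = 0,
    end: int | None = None,
    require_dev: bool = True,
) -> int | None:
    """First iteration in [start, end) satisfying the internal convergence
    rule; ``end`` excludes the finishing phase, whose plain projection passes
    collapse the deviations mechanically.

    Converged at t iff Rfree stayed below ``cfg.r_free_threshold`` over the
    trailing ``cfg.r_free_window`` iterations and (when ``require_dev``)
    both regional density deviations fell below 50% of their trailing
    ``cfg.dev_window`` median.  R-factors and the deviations drop together
    at true convergence, so the combination guards against overfitting
    without reference information.  The deviation-drop clause presumes a
    continuous trajectory; population slots whose density is replaced by
    genetic operations evaluate with ``require_dev=False``.
    """
    n = len(trace) if end is None else min(end, len(trace))
    w = cfg.r_free_window
    if n < w:
        return None
    r_free = trace["r_free"]
    r_ref = np.where(np.isnan(r_free), trace["r_work"], r_free)
    below = r_ref < cfg.r_free_threshold
    dp = trace["dev_protein"]
    ds = trace["dev_solvent"]
    csum = np.concatenate([[0], np.cumsum(below)])
    for t in range(max(w - 1, start), n):
        if csum[t + 1] - csum[t + 1 - w] != w:
            continue
        if not require_dev:
            return t
        lo = max(0, t - cfg.dev_window)
        if t - lo < 10:
            continue
        med_p = np.nanmedian(dp[lo:t])
        med_s = np.nanmedian(ds[lo:t])
        if dp[t] < 0.5 * med_p and ds[t] < 0.5 * med_s:
            return t
    return None


class PhasingEngine:
    """Stateful driver of one phasing trial.

    Keeps the current iterate, envelope mask and metrics trace, and exposes
    ``advance``/``run_finishing`` so the genetic scheme can interleave its
    operations at cadence boundaries.  All randomness derives from
    (cfg.seed, trial) through the stream-splitting rule in :mod:`core`.
    """

    def __init__(
        self,
        rs: ReflectionSet,
        href: HistogramRef,
        cfg: PhasingConfig,
        ctx: GridContext | None = None,
        truth: ComplexSF | None = None,
        true_mask: Mask | None = None,
        trial: int = 0,
    ):
        self.rs = rs
        self.href = href
        self.cfg = cfg
        if ctx is None:
            spacing = cfg.grid_spacing or rs.d_min / 3.0
            grid = choose_grid(rs.cell, rs.sg, spacing, rs.d_min)
            ctx = GridContext(rs, grid)
        self.ctx = ctx
        self.trial = trial
        rng = rng_for(cfg.seed, "init", trial)
        self.rho = ctx.symmetrize(rng.random(ctx.grid))
        self.inside: np.ndarray | None = None
        self.it = 0
        self.finish_step = 0  # > 0 once the finishing protocol has started
        self.trace = MetricsTrace(cfg.n_iter + cfg.n_finish)
        self.failed = False
        if truth is not None:
            nzh = ctx.grid[2] // 2 + 1
            self.F_true = np.ascontiguousarray(ctx.expand(truth.f)[:, :, :nzh])
        else:
            self.F_true = None
        self.true_inside = true_mask.inside if true_mask is not None else None
        self._last_sw = None
        self._weights = None
        self._last_estimate: np.ndarray | None = None
        self.conv_require_dev = True  # GA slots switch this off
        self._finish_trace_start: int | None = None
        self._conv_at: int | None = None
        self._conv_scanned = 0

    # -- schedule helpers ------------------------------------------------

    @property
    def n_main(self) -> int:
        return self.cfg.n_iter - self.cfg.n_finish

    def _current_weights(self) -> np.ndarray | None:
        cfg = self.cfg
        if cfg.scheme == "conventional" or cfg.sigma_w_start == 0.0:
            return None
        sw = sigma_w_schedule(self.it, cfg.n_ramp, cfg.sigma_w_start)
        if sw != self._last_sw:
            self._weights = resolution_weights(self.rs, sw) if sw > 0 else None
            self._last_sw = sw
        return self._weights

    def _update_envelope(self) -> None:
        """Rebuild the protein mask from the current density estimate.

        The smoothed density is taken from the constrained estimate
        PA(PB rho) of the previous step when available: the raw iterate of a
        feedback rule carries correction terms in its solvent region that are
        algorithmic bookkeeping, not density.  The very first mask comes from
        the random start itself.
        """
        cfg = self.cfg
        in_finishing = self.finish_step > 0 or self.it >= self.n_main
        if self.inside is not None and (
            in_finishing or self.it % cfg.envelope_interval
        ):
            return
        sigma = sigma_schedule(
            self.it, max(self.n_main, 1), cfg.sigma_start, cfg.sigma_end
        )
        src = self._last_estimate if self._last_estimate is not None else self.rho
        w = gaussian_weights_grid(src, self.ctx.half_s2, sigma)
        self.inside = mask_from_weights_grid(w, cfg.solvent_fraction)

    # -- one iteration ---------------------------------------------------

    def step(self) -> None:
        if self.failed:
            return
        cfg = self.cfg
        self._update_envelope()
        weights = self._current_weights()

        finishing = self.finish_step > 0 or (
            cfg.n_finish > 0 and self.it >= self.n_main
        )
        if finishing:
            if self._finish_trace_start is None:
                self._finish_trace_start = self.trace.n
            self.finish_step += 1
            n_ramp = max(min(cfg.finish_ramp, cfg.n_finish), 1)
            ramp = max(0.0, 1.0 - self.finish_step / n_ramp)
        else:
            ramp = 1.0
        beta, gamma = _effective_params(cfg.algorithm, cfg.beta, cfg.gamma, ramp)
        new, cache = apply_step_grid(
            cfg.algorithm,
            self.rho,
            self.inside,
            self.href,
            self.ctx,
            beta0=cfg.beta0,
            beta=beta,
            gamma=gamma,
            weights=weights,
        )
        self._last_estimate = cache["papb"]
        self._record(cache)
        if finishing:
            polished, _ = project_fourier_grid(new, self.ctx, weights)
            new = _pa(self.ctx, polished, self.inside, self.href)
        if not np.all(np.isfinite(new)):
            self.failed = True
            return
        self.rho = new
        self.it += 1

    def _record(self, cache: dict) -> None:
        """Record metrics of the current constrained estimate PA(PB rho).

        The raw iterate of a feedback algorithm is an auxiliary quantity
        whose solvent region accumulates corrections; the density estimate
        whose agreement with the data is meaningful is the fully projected
        map, so R factors and phases are computed from it.
        """
        cfg = self.cfg
        rs = self.rs
        F_est = self.ctx.rsf_grid(cache["papb"])
        fcal = ComplexSF(rs.hkl, self.ctx.rgather(F_est))
        try:
            r_work = _metrics.r_factor(rs, fcal, "work")
        except ValueError:
            r_work = float("nan")
        r_free = (
            _metrics.r_factor(rs, fcal, "free") if np.any(rs.free) else float("nan")
        )
        dev_p, dev_s = _metrics.density_deviation_from_cache(
            cfg.algorithm, self.inside, cache
        )
        iou = float("nan")
        if self.true_inside is not None:
            inter = np.logical_and(self.inside, self.true_inside).sum()
            union = np.logical_or(self.inside, self.true_inside).sum()
            iou = float(inter / union) if union else 1.0
        pe = float("nan")
        total = self.trace.n
        if self.F_true is not None and (
            total % cfg.phase_interval == 0 or self.it == cfg.n_iter - 1
        ):
            pe, _ = _metrics.aligned_phase_error(self.ctx, self.F_true, F_est)
        self.trace.append(
            r_work=r_work,
            r_free=r_free,
            phase_error=pe,
            iou=iou,
            dev_protein=dev_p,
            dev_solvent=dev_s,
        )

    # -- drivers ---------------------------------------------------------

    def advance(self, k: int) -> None:
        for _ in range(k):
            if self.failed:
                break
            self.step()

    def run_finishing(self, n_finish: int | None = None) -> None:
        """Run the finishing protocol now (used on GA early termination)."""
        n = self.cfg.n_finish if n_finish is None else n_finish
        if self.finish_step == 0:
            self.finish_step = 1 if n else 0
        self.advance(n)

    def converged_iteration(self) -> int | None:
        """Cached incremental convergence scan (first hit is sticky).

        Only pre-finishing iterations count: the finishing protocol's plain
        PA/PB passes lower the deviations for any state, converged or not.
        """
        if self._conv_at is None:
            end = self._finish_trace_start
            self._conv_at = convergence_iteration(
                self.trace, self.cfg, start=self._conv_scanned, end=end,
                require_dev=self.conv_require_dev,
            )
            self._conv_scanned = len(self.trace) if end is None else end
        return self._conv_at

    def result(self) -> PhasingResult:
        ctx = self.ctx
        rho_map = DensityMap(self.rho.reshape(ctx.grid), self.rs.cell)
        F = ctx.rsf_grid(self.rho)
        phases = ComplexSF(self.rs.hkl, ctx.rgather(F))
        pe = float("nan")
        if self.F_true is not None and not self.failed:
            pe, _ = _metrics.aligned_phase_error(ctx, self.F_true, F)
        try:
            r_work = _metrics.r_factor(self.rs, phases, "work")
        except ValueError:
            r_work = float("nan")
        r_free = (
            _metrics.r_factor(self.rs, phases, "free")
            if np.any(self.rs.free)
            else float("nan")
        )
        conv_at = None if self.failed else self.converged_iteration()
        return PhasingResult(
            map=rho_map,
            phases=phases,
            trace=self.trace,
            converged=conv_at is not None and not self.failed,
            failed=self.failed,
            converged_at=conv_at,
            phase_error=pe,
            r_work=r_work,
            r_free=r_free,
        )


def run_phasing(
    rs: ReflectionSet,
    href: HistogramRef,
    cfg: PhasingConfig,
    truth: ComplexSF | None = None,
    true_mask: Mask | None = None,
    trial: int = 0,
    ctx: GridContext | None = None,
) -> PhasingResult:
    """Run one seeded phasing trial; see :class:`PhasingEngine`.

    A trial whose iterate turns non-finite is marked failed (not raised).
    The result unpacks as ``(map, phases, trace, converged)``.
    """
    engine = PhasingEngine(
        rs, href, cfg, ctx=ctx, truth=truth, true_mask=true_mask, trial=trial
    )
    engine.advance(cfg.n_iter)
    return engine.result()
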