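# Methods

This note documents the models, numerical conventions and design choices
behind `hdmphase`, in the spirit of a statistical-software methods appendix:
what is computed, under which assumptions, and what the built-in synthetic
benchmarks do and do not demonstrate.

## Phase retrieval as alternating projection

The unknown is the unit-cell electron density ρ(r) on a voxel grid.  Two
constraint sets are available:

* **A (real space)** — the density is zero in the disordered-solvent region
  and its value distribution inside the protein envelope matches a reference
  histogram characteristic of proteins at the working resolution.  The
  projector P<sub>A</sub> sets solvent voxels to exactly zero and remaps the
  protein voxels, in rank order, onto the reference quantiles (inverse-CDF
  interpolation at probabilities (i+0.5)/n; ties broken by flattened voxel
  index).  P<sub>A</sub> is idempotent by construction.
* **B (Fourier space)** — the structure-factor amplitudes equal the
  observations.  The projector P<sub>B</sub> rescales every measured
  coefficient to the (optionally resolution-weighted) observed amplitude,
  keeping the calculated phase.  The internal scale is
  λ = Σ<sub>work</sub> w·|F<sub>obs</sub>| / Σ<sub>work</sub> |F<sub>cal</sub>|,
  which makes P<sub>B</sub> exactly idempotent for any fixed weight vector
  and reduces to the ratio-of-sums scale of the R-factor when w ≡ 1.

Reflections without usable observations (the ~1% cross-validation free set,
missing or large-error measurements — σ > 2|F<sub>obs</sub>| — and
reflections below 15 Å resolution) keep their calculated amplitudes, which
is the fill rule |F<sub>miss</sub>| = (Σ|F<sub>obs</sub>|/Σ|F<sub>cal</sub>|)|F<sub>cal</sub>|
expressed on the calculated scale.  Fourier coefficients *outside* the
measured band are set to zero: the density model is band-limited to the
data.  The alternative — carrying unmeasured high-frequency content through
the iteration — was tried and rejected: out-of-band structure introduced by
the sharp-edged real-space projection recirculates through the relaxation
terms and destabilizes the full-strength update rules (the β=γ stability
edge drops from above 1 to ≈0.95).  F(000) is passed through unchanged; the
absolute offset is unobservable, and the (positive) reference histogram
pins it in real space.  A zero-mean F(000)=0 convention was also tried and
rejected: it removes the protein/solvent contrast on which the envelope
estimator depends and degrades every algorithm sharply.

All eight update rules (the table in the README) are built from one shared
pair of projector implementations; each step performs exactly one
P<sub>B</sub> evaluation, and P<sub>A</sub>P<sub>B</sub>ρ / P<sub>A</sub>ρ
are evaluated at most once each and reused by the convergence metrics.  At
β₀ = 1 the two-candidate difference-map step is implemented in its
simplified global form ρ + (2P<sub>A</sub>P<sub>B</sub> − P<sub>A</sub> −
P<sub>B</sub>)ρ, as the derivation treats it; for β₀ ≠ 1 the two-candidate
form is used as written.

Iteration is carried on the full unit-cell grid in P1; space-group symmetry
is enforced by averaging over the symmetry operations after every
real-space projection.  Grids are chosen 2,3,5-smooth, even, strictly finer
than twice the resolution limit, and compatible with all symmetry
translations.  The hot path uses real-to-complex FFTs on the half spectrum.

## Envelope determination

The protein mask is rebuilt every 10 iterations (configurable) by smoothing
the current density with a periodic Gaussian — σ decreasing linearly from
4.0 Å to 2.5 Å over the pre-finishing iterations — and keeping the
highest-weighted (1 − solvent fraction) of voxels.  The smoothing source is
the constrained estimate P<sub>A</sub>(P<sub>B</sub>ρ) of the previous
step, not the raw iterate: the raw iterate of a feedback rule carries
correction terms in its solvent region that are algorithmic bookkeeping,
not density, and masks derived from it are visibly worse.  The mask is
frozen during the finishing phase.

## Monitoring and the convergence verdict

R<sub>work</sub>/R<sub>free</sub>, the mean phase error (when reference
phases are supplied) and the envelope IoU are computed from the constrained
estimate P<sub>A</sub>(P<sub>B</sub>ρ<sub>n</sub>) at every iteration, for
the same reason: the raw iterate's amplitudes never converge to the data
even for a perfectly solved structure (its work-set R sits near 0.7
throughout), whereas the estimate's R factors drop sharply at the
convergence phase transition.  The region-wise density deviations are the
mean absolute value of each rule's own relaxation bracket over the protein
region (2P<sub>A</sub>P<sub>B</sub>−P<sub>A</sub>−P<sub>B</sub> for the
f1/f2 family and the difference map; P<sub>A</sub>P<sub>B</sub>−P<sub>A</sub>
for f3/f4; P<sub>A</sub>P<sub>B</sub>−P<sub>B</sub> for f5/f6;
P<sub>A</sub>P<sub>B</sub>ρ−ρ for HIO) and of |P<sub>B</sub>ρ| over the
solvent, reusing the step's cached operator evaluations.

In space groups with floating origins a raw phase comparison is
meaningless, so the trace's phase error is evaluated after searching the
solution-degeneracy group — allowed origin shifts (continuous along polar
axes, discrete otherwise) and, in non-centrosymmetric groups, the
enantiomer inversion — by FFT cross-correlation with parabolic sub-voxel
peak interpolation, followed by a weighted least-squares refinement of the
sub-voxel origin against the residual phase gradients.  The alignment
residual contributes well under 1° of apparent phase error.

A trial is declared **converged** when R<sub>free</sub> (computed from the
estimate) stays below 0.35 over a sustained trailing window *and* both
density deviations fall below 50% of their trailing-window median — the
phase-transition signature.  Only pre-finishing iterations count: the
finishing protocol's plain projection passes collapse the deviations for
any state, converged or not.  The deviation-drop clause presumes a
continuous trajectory; population slots whose density is replaced by
genetic operations are judged by the sustained-R<sub>free</sub> clause
alone.  The library default window is 200 iterations (sized for runs of
order 10⁴ iterations); the built-in desk-scale studies, which run 2000
iterations, use 100.

Success for the benchmark studies means this verdict fired.  Final phase
error alone would be misleading on the noise-free toy: the finishing stage
(density modification from whatever state) partially rescues non-converged
states, while the verdict counts genuine convergence events as the traces
show them.

## Finishing protocol

During the last `n_finish` iterations (500 by default) the update rule is
gradually turned off and solvent flattening takes over: the relaxation and
feedback factors ramp linearly to zero over the first 50 finishing
iterations, and every finishing iterate is followed by a plain
P<sub>A</sub>(P<sub>B</sub>·) pass.  The ramp is kept short deliberately: a
ramp spread over all 500 iterations sweeps an over-driven run (β=γ≈1.4)
slowly through the productive parameter range and converges states that the
main iteration never solved — an annealing effect that would erase the
parameter-sensitivity structure the method is known for.

## Genetic evolution scheme

A population (default 100; 20 in the desk-scale studies) of independent
trials advances in lockstep and exchanges information every 100 iterations:

* fitness f = (R<sub>thres</sub> − R<sub>work</sub>)/(R<sub>thres</sub> −
  R<sub>min</sub>) clamped to [0,1], with the adaptive threshold
  R<sub>thres</sub> = R<sub>avg</sub> + (R<sub>avg</sub> − R<sub>min</sub>);
* roulette-wheel parent selection, with near-duplicate individuals
  (density correlation > 0.98 with a fitter one) penalized by halving,
  elites exempt;
* multi-segment crossover: five random axis-aligned periodic boxes whose
  union covers 50% ± 2% of the grid (a global scale factor is bisected to
  hit the target) are swapped between two parents;
* mutation: each voxel replaced with Uniform[0,1] with probability 1%;
* elitism (3 of 20 in the studies; 5 at population 100).

Before any crossover, every individual is aligned to the fittest over
allowed origin shifts plus the enantiomer flip, scoring by *density*
correlation.  Mask overlap alone cannot resolve the enantiomer hand of a
compact (nearly centrosymmetric) envelope, and crossover between opposite
hands produces meaningless offspring; density correlation subsumes mask
overlap for maps of a common structure.

Replacement policy: elites, already-converged slots, slots whose
R<sub>work</sub> is already at the converged level (within 1.2× of the
median converged R<sub>work</sub>), and freshly inserted offspring younger
than two cadence periods are protected; all other slots receive new
offspring each generation.  Without the maturation period the driver
livelocks: every offspring is replaced before its convergence window can
complete.  Once every individual is converged the evolution terminates
early and each individual runs the finishing protocol.  The chromosome grid
is the phasing grid itself; the studies use ~1 Å voxels, so no resampling
step is needed.  Individuals advance independently between cadence points;
a process-pool backend reproduces the serial results bit-for-bit given the
same seeds.

## Synthetic toy crystals

`make_toy_crystal` places Gaussian pseudo-atoms (σ 0.65–0.9 Å — the
B-factor-broadened effective atom width of ~2 Å data; weights 0.5–1)
uniformly in a sphere whose volume matches the requested protein fraction,
symmetrizes, flattens the solvent of the band-limited blob map and
band-limits again.  Observed amplitudes are |F| of that true map exactly;
truth phases, the true mask, and a reference histogram (the true protein
region's own quantiles) are returned.  The blob width matters: much wider
blobs leave essentially no amplitude at the band edge, making the
equal-weight mean phase error floor ~36° (high-resolution phases carry no
information); much narrower ones make the toy unsolvable for every rule.

The true map's solvent carries ~1% series-termination ripple — a
band-limited map cannot vanish exactly on 70% of the voxels, because the
measured band holds fewer real degrees of freedom than there are solvent
constraints.  For the operator-algebra tests a dedicated fixture
(`exact_fixed_point=True`) therefore uses a small protein-rich crystal
(solvent 40%, Nyquist grid, P1), where the intersection is non-empty and a
dense least-norm solve produces a map that is simultaneously band-limited,
exactly solvent-flat and histogram-locked: an exact common fixed point of
both projectors, which all eight update rules preserve to better than
10⁻⁸.  `add_noise` applies relative Gaussian amplitude noise with matching
σ(F) columns for exercising the flagging rules.

What the toys do not emulate: measurement noise on the benchmark data
(amplitudes are exact), atomic-resolution detail beyond the Gaussian blob
model, B-factor gradients, bulk-solvent scattering, data incompleteness
beyond the flagged subsets, and crystal-packing envelopes more convoluted
than a blob cluster.  Passing the desk-scale studies shows the machinery
and the algorithms' relative behavior, not performance on deposited
diffraction data; `scripts/benchmark_full.py` sketches the full-scale run
for users with real reflection files.

## Desk-scale study conditions

One benchmark toy: P1, 30 Å cube, 28 blobs, 70% solvent, d = 2 Å data
(7070 unique reflections), 1 Å grid (30³).  Single-trial schemes run 20
seeded trials × 2000 iterations (500 finishing); the genetic scheme runs
one population of 20 with a 3000-iteration ceiling and early termination;
the resolution-weighted schedule ramps σ<sub>w</sub> from 0.8 Å to 0 over
600 iterations (30% of the run, matching the proportion used at full
scale).  Parameterized rules run at β = γ = 0.75.  On this toy the
parameterized hybrid rules (f2/f3/f4/f6 at 0.75), HIO and the difference
map converge reliably to final phase errors of 10–25°; γ = 0 never
converges (the solvent feedback is the driving force), and β = γ = 1.4 sits
past the stability edge.  The parameter-free f1 (β = γ = 1) does not
converge from random starts on this toy even though it preserves the exact
solution and is locally stable there — in this implementation the β=γ
stability edge sits near 0.95, and exact rank-order histogram matching
(a harder projection than softened histogram-matching variants) is the
suspected reason the edge is lower than reported elsewhere.

## Known limitations

* Space-group support covers what the symmetrization, origin-shift and
  centricity machinery derives from the operator lists; only P1 and
  P2₁2₁2₁ paths are exercised by tests.
* The GA collective-convergence lag after the first individual converges is
  6–8 cadence periods in the studies (offspring need ~2 cadences to lock
  plus the verdict window; failed insertions retry on the maturation
  clock), somewhat slower than the idealized 5.
* Phase error is unweighted (mean over the work set); amplitude-weighted
  variants would read lower on weak-amplitude-rich data.
* Intensities-to-amplitudes reduction, anomalous data and twinning are out
  of scope; inputs are amplitude files (plain-text dialect or MTZ).
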