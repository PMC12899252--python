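# hdmphase

Ab initio phasing of protein crystal diffraction data by iterative
projection, built around the **hybrid difference map (HDM)** family of
update rules, with the classic hybrid input–output (HIO) and difference-map
(DiffMap) algorithms as baselines.

## The problem

A diffraction experiment measures only structure-factor amplitudes
|F<sub>obs</sub>(h)|; the phases φ(h) needed to compute the electron density
ρ(r) are lost.  When the crystal contains a large disordered-solvent
fraction, the density is strongly constrained in real space — flat in the
solvent region, and with a characteristic value distribution (histogram)
inside the protein envelope — and phases can be recovered *ab initio* by
iterating between two projections:

* **P<sub>A</sub>** (real space): flatten the solvent region to zero and
  rank-remap the protein-region density onto a reference histogram;
* **P<sub>B</sub>** (Fourier space): replace calculated amplitudes by
  |F<sub>obs</sub>|, keep calculated phases; reflections without usable
  observations are filled from calculated values,
  |F<sub>miss</sub>| = (Σ|F<sub>obs</sub>|/Σ|F<sub>cal</sub>|)·|F<sub>cal</sub>|.

The update rules combine these projections per region (S = protein mask,
estimated on the fly by thresholding a Gaussian-smoothed map at the known
solvent fraction):

| rule | protein region r ∈ S | solvent region r ∉ S |
|---|---|---|
| DiffMap (β₀=1) | ρ + (2P<sub>A</sub>P<sub>B</sub> − P<sub>A</sub> − P<sub>B</sub>)ρ | ρ − P<sub>B</sub>ρ |
| HIO | P<sub>A</sub>P<sub>B</sub>ρ | ρ − γP<sub>B</sub>ρ |
| HDM-f1/f2 | P<sub>A</sub>P<sub>B</sub>ρ + β(2P<sub>A</sub>P<sub>B</sub> − P<sub>A</sub> − P<sub>B</sub>)ρ | ρ − γP<sub>B</sub>ρ |
| HDM-f3/f4 | P<sub>A</sub>P<sub>B</sub>ρ + β(P<sub>A</sub>P<sub>B</sub> − P<sub>A</sub>)ρ | ρ − γP<sub>B</sub>ρ |
| HDM-f5/f6 | P<sub>A</sub>P<sub>B</sub>ρ + β(P<sub>A</sub>P<sub>B</sub> − P<sub>B</sub>)ρ | ρ − γP<sub>B</sub>ρ |

(f1/f3/f5 are the parameter-free forms, β = γ = 1.)  Three phasing
strategies drive the iteration: the conventional full-resolution scheme, a
resolution-weighted scheme that feeds amplitudes through a shrinking
Gaussian low-pass filter exp(−2(πσ<sub>w</sub>S<sub>h</sub>)²), and a
genetic-evolution scheme that runs a population of trials exchanging
density segments between aligned individuals, with an R<sub>work</sub>-based
dynamic fitness, 1% mutation, elitism and early termination.  Convergence is
monitored by R<sub>work</sub>/R<sub>free</sub>, the mean phase error
Δφ = ⟨arccos cos(φ<sub>true</sub> − φ<sub>cal</sub>)⟩ against reference
phases, envelope IoU, and region-wise density deviations that require no
reference.  Independently converged maps are aligned over allowed origin
shifts (and the enantiomer flip) and averaged to reduce the final phase
error.

Everything runs on synthetic toy crystals generated by
`hdmphase.synthetic.make_toy_crystal`: Gaussian pseudo-atoms in a periodic
cell with exact amplitudes and known true phases, so every claim is testable
against ground truth.

## Worked example

```sh
hdmphase simulate --cell 30 --blobs 28 --solvent-fraction 0.70 --d-min 2.0 \
    --seed 1 --out toy/
hdmphase phase --reflections toy/reflections.txt --histogram toy/histogram.txt \
    --truth toy/truth.txt --algorithm hdm_f2 --beta 0.75 --gamma 0.75 \
    --n-iter 2000 --n-finish 500 --solvent-fraction 0.70 --grid-spacing 1.0 \
    --seed 0 --trials 2 --out run/
```

The first command prints

```
wrote 7070 reflections, d_min 2.00 A, protein fraction 0.300 -> toy/
```

(7070 symmetry-unique reflections to 2 Å for the 30 Å P1 cell, and a
protein envelope occupying 30% of the cell).  The second runs two seeded
trials and prints a summary like

```json
{
  "algorithm": "hdm_f2",
  "scheme": "conventional",
  "n_trials": 2,
  "n_success": 2,
  "success_rate": 1.0,
  "median_iterations": 743.0,
  "phase_error_deg": [11.86, 23.81],
  "r_free": [0.052, 0.202]
}
```

Both trials converged (the internal verdict fired around iteration 743);
their final mean phase errors against the known truth are 11.9° and 23.8° —
essentially correct maps, the first more fully polished (free R 0.05 vs
0.20).  A failed trial would instead stagnate near the 90° random-phase
level with a free R above 0.35.  Per-trial
traces (`trace_000.csv`: R<sub>work</sub>, R<sub>free</sub>, phase error,
IoU, density deviations per iteration) and phase files are written next to
the summary; `hdmphase average` aligns and averages converged maps, and
`hdmphase metrics` scores any phase file against a reference.

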