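# Methods

This note documents the models, numerical choices and limitations behind
`quadtune`: the benchmark functions and trial protocol, the optimizers, the
virtual instrument, the calibration loops, and the tuning pipeline.

## Benchmark functions and instances

Two formula-defined multimodal test functions are implemented, both of the
"shifted and rotated" family used in evolutionary-computation benchmarking:

* **F5 — shifted/rotated Rastrigin.**
  `f(x) = 500 + Σ (z_i² − 10 cos 2πz_i + 10)` with
  `z = M · (0.0512 (x − o))`.
* **F7 — shifted/rotated Lunacek bi-Rastrigin.**
  `f(x) = 700 + min(Σ(x̂_i − μ₀)², dD + s Σ(x̂_i − μ₁)²) + 10(D − Σ cos 2πẑ_i)`
  with `x̂ = 2 sign(o) y + μ₀`, `y = 0.1 (x − o)`, `ẑ = M (x̂ − μ₀)`,
  `μ₀ = 2.5`, `d = 1`, `s = 1 − 1/(2√(D+20) − 8.2)`,
  `μ₁ = −√((μ₀² − d)/s)`.  For the degenerate case `D = 1` the scale `s`
  turns negative; it is clamped at 0.2, which preserves the global minimum
  at the shift.  Note the two members use their standard, *different*
  domain shrink factors (5.12/100 for Rastrigin, 10/100 for bi-Rastrigin).

The search domain is `[−100, 100]^D`.  Instances are generated from a seed:
the shift `o` is uniform over the inner 80% of the domain and the rotation
`M` is a sign-fixed QR orthogonalization of a standard-normal matrix.  The
constructions guarantee `f(o) = bias` exactly, which is both a test
invariant and the first pair of reproduced quantities.  Hybrid/composition
suite members whose internals are defined by external data files (F16, F20,
F26, F29) are rejected at the API boundary instead of being approximated.

Because instances are self-generated rather than loaded from the official
benchmark data files, 30-trial means are comparable to published tables
only up to instance/trial variability; the test suite therefore asserts
band membership (reference mean ± reported trial std) and the qualitative
ranking of algorithms, not exact values.

**Trial protocol.**  `run_trials` derives one `SeedSequence` child per
trial from the master seed and splits it into an instance seed and an
optimizer seed, so results are bit-reproducible.  A trial's score is the
best objective value found during the run (best-of-run, not
final-population mean); the reported std is the sample std (n − 1).  The
protocol used throughout is D = 10, N = 20, G = 25, 30 trials — an
evaluation budget of 520 per run, deliberately tight to mirror the spectra
budget of a real tuning session.

## Optimizers

All optimizers minimize over a box, evaluate `N (G + 1)` candidates, and
draw every random number from one seeded `numpy` generator in a fixed,
documented order (per generation, per individual in stored order: mutation
draws, then D crossover uniforms, then the forced crossover index).

Design choices that were genuinely open:

* **Generation index.** `g` runs 0…G−1 during mutation and `g/G` enters the
  factor schedules as a real ratio, so `F₁ ∝ (1 − g/G)²` reaches zero only
  in the limit and `F₃` runs from `α₂ + α₃` down to just above `α₂`.
* **Ranking without reordering.** The improved DE determines ELS/MIS/INS
  membership from the fitness ranking but processes individuals in stored
  order.  This is behaviourally equivalent to physically sorting the
  population (selection is per-individual) and makes the collapse onto
  DE/rand-to-best/1/bin exact on a shared draw sequence — the reduction
  oracle asserted in the tests.
* **Subpopulation rounding.** `|ELS| = round(r_E N)`, `|INS| = round(r_I N)`,
  `|MIS| = N − |ELS| − |INS|`; if a set would be empty at `N ≥ 10` one
  member is moved from the largest set.  The ratios are exact at `N = 20`.
  An explicit ratio override used by the reduction oracle is taken
  literally.
* **Donors.** Elite-rule donors are drawn from the whole population,
  distinct from each other, the target and the incumbent best; middle-rule
  donors exclude only the target.  The random factor in `F₁` is re-sampled
  per mutant, preserving within-generation diversity.
* **Uniform pipeline.** Inferior-subpopulation restarts still pass through
  crossover, boundary clipping and greedy selection, so a restart only
  survives if it actually improves.
* **Selection** requires strict improvement; ties keep the target.
  Synchronous update: all trials of a generation compete against the
  previous generation's survivors, and the incumbent best is refreshed once
  per generation.
* **Classic-DE constants.** `F = 0.5` and `λ = 0.5` (mid-range convention);
  `CR = 0.75` everywhere.  PSO uses `c₁ = c₂ = 2`, velocity clamped to 20%
  of each coordinate's range, inertia `w = 0.9 − 0.5 g/G`, pbest/gbest from
  the initial swarm, velocities initialized to zero.

Non-goals: self-adaptive parameter control (JADE/SHADE-style archives),
population-size reduction, constraint handling beyond box bounds,
maximization (callers negate).

## Virtual instrument

The simulator is an explicit stand-in for the physical plant, not an
ion-optics model; no Mathieu stability analysis, chromatography, isotope
structure or detector saturation is attempted.  Its purpose is to provide a
plant with *known* ground truth so that tuning behaviour is testable.

* **Intensity response.**
  `I(p) = I_max Π_p exp(−(p − p*)²/(2σ_p²)) · (1 + ε)`, clipped at zero —
  separable and unimodal per parameter, the behaviour univariate search
  assumes.  In interaction mode (the default for comparative experiments)
  DP and EP share a rotated covariance with correlation ρ = 0.6, so their
  joint optimum is off every axis-aligned search path.  Defaults: bounds
  CUR, GS1 ∈ [5, 40], DP ∈ [50, 200], EP ∈ [2, 15]; ground truth
  p* = (20.229, 15.573, 163.03, 11.413); widths σ = (6, 6, 30, 2.5).
  These are synthetic fixtures chosen to be of realistic magnitude, not
  claims about any real instrument.
* **Axes.**  Mass→DAC and FWHM→OFFSET characteristics are linear with
  invented coefficients (DAC(m) = 500 + 35 m counts;
  FWHM = 0.7 + 0.05 (OFFSET − OFFSET₀(m)) u with
  OFFSET₀(m) = 1.5 + 0.004 m V).  The instrument boots detuned: initial
  mass errors (0.103, 0.15, 0.25) u and initial widths
  (1.239, 1.313, 1.945) u.  Weak couplings (DP→centroid 0.0008 u/V,
  EP→FWHM 0.008 u/V about the parameter midpoints) make re-calibration
  after a parameter change genuinely necessary.
* **Noise.**  Multiplicative Gaussian intensity noise with CV = 0.06 per
  single scan (default); centroid/FWHM readings jitter with
  sd = 0.2·CV u.  All noise scales with one knob, so CV = 0 yields a fully
  deterministic plant.  Intensities are MCA accumulations (sum of
  `mca = 5` single scans), which lowers the effective intensity CV to
  ≈ CV/√5; single-scan maxima (5.28·10⁶, 5.22·10⁶, 1.578·10⁶ cps) were
  chosen so MCA-5 readings sit in the 10⁶–10⁷ cps range typical of NaI/CsI
  calibrant peaks at m/z 172.88 / 622.57 / 922.36.
* **Spectra.**  Peaks render as area-normalized Gaussians (trapezoid
  integral equals the reported intensity within 1%); export is two-column
  text.

What passing tests on this plant do *not* show: performance on real
hardware, where the response surface is neither Gaussian nor stationary,
noise is not purely multiplicative, and peak shapes are asymmetric.  The
simulator supports the algorithmic claims (relative ranking of optimizers,
calibration convergence, repeatability of the procedure), not absolute
intensity claims.

## Calibration loops

Both loops are the proportional update above.  The gain is estimated at
startup by a two-point probe (perturb the setting by `probe_step` — 10 DAC
counts or 4 V — re-measure, invert the fitted slope); on the noiseless
plant this recovers the matched gain and converges in one step (deadbeat).
Under noise a single measurement per iteration is used (an averaging knob
exists); the probe steps are large enough that the relative slope error
stays below ~20%, giving a contraction factor comfortably inside the unit
circle — 100 seeded runs of each loop converge within 20 iterations in
≥ 99% of cases (asserted).  Non-convergence is a reported status, not an
exception, so the tuning loop can score a failing candidate as +∞ and move
on; an error that grows three iterations in a row is flagged divergent
(wrong gain sign).  Calibration touches only the per-peak DAC/OFFSET
settings, never the tuning parameters.

## Tuning pipeline

Candidate vectors are clipped to bounds *before* being applied to the
instrument.  By default every candidate triggers per-peak recalibration
(all tuning parameters are treated as potentially peak-shifting); an
economy mode recalibrates once per generation block.  The univariate
baseline does a single pass in the order GS1, CUR, DP, EP over a 10-level
uniform grid per parameter (endpoints included), locking in each winner —
multi-pass refinement is deliberately off, matching the single-pass
behaviour of common vendor auto-tune routines.  Both methods share the
same candidate evaluator, so their fitness values are directly comparable;
the final result re-applies the winning parameters, recalibrates and
re-measures, which is why every reported peak satisfies both tolerances.

The file-exchange protocol is plain ASCII `key=value` with a monotonically
increasing sequence number and atomic rename on write; readers poll until
the peer's sequence advances or a timeout fires.  The format is an
implementation choice — the original design only fixes "text files".

## Problem sizes used in tests and the reproduction script

Benchmark statistics use the full protocol (30 trials × 520 evaluations).
The tuning comparison uses 20 paired seeds, parameter recovery 20 noiseless
seeds, and the repeatability study 10 noisy runs — sizes chosen as the
smallest at which the stochastic properties under test (win rates ≥ 90%,
CV bounds) are stable across master seeds.  The reproduction script
(`scripts/acceptance.py`) re-derives every reported number at run time from
its `--seed`; nothing is cached or hard-coded.

## Known limitations

* Benchmark means depend on the self-generated instance distribution; they
  track published 30-trial statistics only within one trial-std band.
* The improved DE's advantage is budget-dependent: with generous budgets
  (thousands of evaluations) classic DE variants catch up on these
  low-dimensional problems.
* The univariate baseline's deficit is a function of the configured DP–EP
  correlation (ρ = 0.6); a separable plant (interaction off) removes it by
  construction.
* The file protocol is single-producer/single-consumer and polling-based;
  it is a faithful minimal model of script-level instrument integration,
  not a general IPC mechanism.
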