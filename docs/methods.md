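# Methods

This note records the modelling conventions, numerical choices and known
limitations behind the package.  Notation: an uncertain parameter θ on a
finite support [a, b] with unknown CDF F; a p-box is the pair
(F̲, F̄) with F̲ ≤ F ≤ F̄ pointwise.

## P-box construction

The four primitive constructions (support only; + median m; + mean μ;
+ mean and SD σ) are closed-form and tight: each bound value is attained
by some distribution satisfying the statistics.  Tightness is not taken
on faith — the test suite compares the closed forms against a linear
program that optimizes P(X ≤ t) over discrete distributions on a grid of
the support subject to the same constraints, and requires agreement
within 5·10⁻³ at a 201-point grid.  The LP grid is augmented with atoms
at the query point t and at t ± 10⁻⁹(b−a), because the extremal
distributions concentrate mass exactly at or just beyond the threshold;
without those atoms the grid bias (~2·10⁻²) swamps the comparison.

Conventions and edge cases:

* **Right continuity.**  All bounding functions are right-continuous;
  a breakpoint belongs to the segment on its right.  Consequently the
  median construction with m = a evaluates to F̲(a) = ½ — the tight
  value, since a median at the lower endpoint forces P(X ≤ a) ≥ ½.
* **Moment feasibility** σ² ≤ (μ−a)(b−μ) is enforced when a record is
  created; it is exactly the condition ξ₁ ≥ a and ξ₂ ≤ b that keeps the
  four segments ordered.  σ = 0 (or μ at an endpoint) degenerates to the
  unit step at μ.
* **Richer statistics** (median and mean together, with or without SD)
  are built as the pointwise intersection of the applicable primitives.
  Crossing of the intersected bounds on a 2001-point grid is treated as
  joint infeasibility and rejected.  The crossing test is a necessary
  condition only: a median/mean/SD triple can be infeasible on a bounded
  support without crossing these particular bounds, which is why the
  feasibility authority in the fixture generator is the LP, not the
  intersection.
* **Quasi-inverse.**  left(p) = inf{θ : F̄(θ) ≥ p} and
  right(p) = sup{θ : F̲(θ) ≤ p}, clamped to [a, b], computed by bisection
  on the monotone bounds with tolerance 10⁻¹⁰(b−a) and snapped to nearby
  breakpoints so step-function inverses are exact.  At p = 0 the left
  endpoint is a by definition — the bottom probability slice therefore
  always reaches the support minimum.  Closed-form inverses would be an
  optimization only; bisection is the normative path because it handles
  flat segments and jumps without case analysis.
* Unbounded supports, and records lacking a or b, are rejected:
  every implemented formula assumes a finite interval.

## Discretization and propagation

Slicing partitions [0, 1] into n sub-intervals (equal masses 1/n by
default; any positive mass vector summing to 1 is accepted) and maps
each sub-interval (c, d] to the parameter interval
[left(c), right(d)] — the *outer* discretization, which never
under-covers.  Inner or intermediate endpoint choices are recognized in
the interface but deliberately not implemented.  Joint structures are
full-factorial products with product masses, i.e. random set
independence; parameter dependence (copulas) is out of scope.

Per-hyperrectangle optimization of the model:

* `grid` — full factorial grid, g = 21 points per varying dimension by
  default, endpoints included.  Used as the oracle in tests (≤ 3
  dimensions) and throughout the shipped case study, where the model is
  vectorized and cheap.
* `direct` — the deterministic dividing-rectangles (DIRECT) global
  search, via `scipy.optimize.direct`, budget 500·dimension evaluations
  per bound; box vertices are evaluated first so the incumbent is never
  worse than the vertex heuristic.  DIRECT samples rectangle centres and
  never the boundary.
* `vertex` — two evaluations per box; requires a declared monotonicity
  direction for every p-box parameter and raises if the declared
  directions produce inverted bounds.

The outcome p-box cumulates the mass of each per-box *minimum* into the
upper bound F̄(Y) and of each *maximum* into the lower bound F̲(Y); this
is the only labelling for which F̲ ≤ F̄.  Expected-value intervals use
the record form [Σ P·Y̲, Σ P·Ȳ], which is exact for any utility already
composed into the model and avoids integrating a possibly non-monotone
utility against the bound labels.

**Infinite extremes.**  Some functionals are genuinely unbounded on
closed boxes: the four-state residence time diverges as the exit rate
c6 → 0, and the bottom slice of any p-box whose support starts at 0
contains that point.  Model outputs of ±∞ are therefore carried through
the records as honest extremes; only NaN is an error.  Staircase grids
span the finite record range, so an infinite-mass tail simply keeps the
lower bound below 1 at the top of the grid; expectation intervals report
the infinity.  A DIRECT-only analysis reports large finite incumbents
instead — an inner approximation inherent to sampling-based optimizers,
not a tighter truth.

**Mixed parameter sets.**  Parameters with precise CDFs are propagated
by plain seeded Monte Carlo: N joint draws, one optimization pass per
draw, and the per-draw staircases averaged pointwise — implemented as
the weighted ECDF of the pooled records with masses divided by N, which
is identical to the average.  `fix_at_mean` replaces the sampling loop
with a single pass at the distribution means; it is exact for models
linear in those parameters and a documented approximation otherwise.
With no p-box parameters the machinery reduces to ordinary PSA
(lower = upper = the empirical outcome CDF); with no CDF parameters it
reduces to pure p-box propagation regardless of N.

## Cohort models

The four-state chain S1→{S2,S3,S4}, S2→{S3,S4}, S3→S4 with S4 absorbing
is parameterized by six nonnegative rates used directly in a
continuous-time generator (no rate-to-probability conversion).  Expected
residence time in {S1,S2,S3} is π₀ᵀ(−Q_T)⁻¹1 over the transient states
*reachable from the initial support* — restricting to reachable states
is what makes configurations with unreachable branches (rates set to 0)
well-posed.  If absorption is not almost sure from the initial support
the closed form raises a model error; the vectorized wrapper used in
propagation instead returns +∞, the true value of the limit, so
optimizers can probe closed boxes.  The rate c3 is assigned to the
direct S1→S4 arc, the only arc not otherwise named.  An independent
ODE-integration oracle checks the closed form to 10⁻⁶ relative in tests.

The cost-effectiveness engine iterates a cohort trace over named states
with per-cycle transition matrices (rows validated to sum to 1 within
10⁻⁹, entries in [0, 1], violations reported with the offending row).
Costs and utilities are *per-cycle* accruals credited at cycle end and
discounted by (1 + r_annual)^(−cycle·months/12); a half-cycle option
averages adjacent occupancies and is off by default.  INMB is
λ·ΔQALY − ΔCost.  The shipped nine-state knee-replacement-shaped config
(`pba.examples.synthetic_cea_config`) is a synthetic look-alike with
plausible placeholder values — it exercises the pipeline end to end and
replicates no published table.

## What the synthetic fixtures do and do not show

`sample_consistent_distribution` draws a vertex of the LP feasible
polytope (random linear objective, seeded), so every generated
distribution satisfies its record's statistics to solver precision
(~10⁻⁹ on means, 10⁻⁶ relative on SDs) but is supported on a 201-point
grid.  Passing enclosure tests therefore demonstrates the bounds hold
for a rich, randomly varied family of discrete distributions — they
generalize to continuous distributions by the closed-form nature of the
bounds, but the tests themselves never exercise densities, heavy
smoothing, or real-world measurement error.  `random_minimal_data`
keeps means 5% away from the support endpoints and SDs between 10% and
90% of the feasibility cap — representative records rather than
degenerate corners — and certifies median/mean(/SD) combinations with
the LP before returning them.

Empirical-sample enclosure uses the two-sided
Dvoretzky–Kiefer–Wolfowitz band at confidence 0.999
(ε = √(ln(2/0.001)/2n)); exact-CDF comparisons use an absolute
tolerance of 10⁻⁹ on probabilities.

## Problem sizes

The default analysis sizes are chosen to match what the method needs,
not more: 50 slices per parameter (2,500 hyperrectangles) for the
four-state case study with the g = 21 grid optimizer; 100,000 PSA draws
for empirical comparisons; 200 record/distribution pairs for the
enclosure sweep; convergence assessed at n ∈ {5, 10, 25, 50} on a fixed
common outcome grid (each run's own staircase grid spans a different
finite range, so areas are compared on a shared one).

## Known limitations

* Outcome bounds from black-box propagation are conservative but not
  optimal; no tightness guarantee exists at the output side.
* Independence between parameters is assumed throughout (product
  masses); dependence modelling is out of scope.
* Multi-outcome models are propagated one outcome at a time; the
  bounds are marginal, not joint.
* Median-case tightness is inherent to the half-step construction and
  is only informative at the 0.5 level.
* No parametric p-boxes (distribution families with interval
  hyperparameters) and no confidence-band constructions from raw
  samples; the package covers free p-boxes from summary statistics.
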