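# pba — probability bounds analysis for decision-analytic models

Decision-analytic and cost-effectiveness models are routinely run with
parameters whose probability distributions are unknown: often all the
literature offers is a plausible range, sometimes a mean or a median,
occasionally a standard deviation.  Probabilistic sensitivity analysis
(PSA) forces the analyst to invent a full distribution anyway.  This
package implements the distribution-free alternative, **probability
bounds analysis (PBA)**: each uncertain parameter is represented by a
**probability box** (p-box) — a pair of bounding CDFs
F̲(θ) ≤ F(θ) ≤ F̄(θ) containing *every* distribution consistent with the
available summary statistics — and the p-boxes are propagated through
the model without further assumptions.  It is aimed at health-economics
and epidemiological modellers, but nothing in it is specific to health.

## What it computes

**P-box construction.**  For a parameter on a known support [a, b] the
tightest bounds are closed-form:

* {a, b} only — unit steps at the endpoints (the vacuous box);
* {a, b, m} (median) — half steps: F̲ = ½ on [m, b), F̄ = ½ on [a, m);
* {a, b, μ} (mean) — Markov-type ratios, e.g. F̲(θ) = (θ−μ)/(θ−a) on [μ, b);
* {a, b, μ, σ} — four-segment Cantelli-type bounds joined continuously at
  ξ₁ = μ − σ²/(b−μ) and ξ₂ = μ + σ²/(μ−a);
* richer combinations — pointwise intersection (max of lower bounds, min
  of upper bounds), with jointly infeasible statistics rejected.

**Propagation.**  Each p-box is sliced into probability intervals
(outer discretization via the quasi-inverses of the bounds); the
Cartesian product of slices across parameters gives hyperrectangles with
product masses (random set independence).  A deterministic black-box
model Y = ℳ(θ) is minimized and maximized over every hyperrectangle
(dividing-rectangles global search, an exhaustive grid oracle, or a
two-vertex rule for declared-monotone models); cumulating the masses of
the minima yields F̄(Y), of the maxima F̲(Y).  Parameters with precisely
known CDFs are handled by Monte Carlo around the optimization loop, or
fixed at their means as a shortcut for near-linear models.

**Decisions.**  The expected value of Y over a p-box is an interval
[μ̲, μ̄] = [Σₖ P(ℋₖ)·Y̲ₖ, Σₖ P(ℋₖ)·Ȳₖ]; interventions are compared by
interval dominance, the pessimist rule (max μ̲), the optimist rule
(max μ̄), or the Hurwicz criterion (max α·μ̲ + (1−α)·μ̄).

Built-in models: a four-state continuous-time cohort model (expected
residence time before absorption) and a discrete-cycle Markov
cost-effectiveness engine producing incremental net monetary benefit
(INMB) at a willingness-to-pay threshold, with discounting.

## Worked example

Two transition rates of the four-state cohort model are known only
through summary statistics; the remaining rates are fixed.  The outcome
is the expected time spent outside the absorbing state:

```python
import pba
from pba.cohort import residence_black_box

d = pba.MinimalData(a=0.0, b=10.0, mean=1.0, sd=0.0167)
p = pba.make_pbox(d)
print("bounds at 0.99:", pba.eval_bounds(p, 0.99))
# bounds at 0.99: (0.0, 0.7360711552165532)

model = residence_black_box(
    c1_data=pba.MinimalData(0.0, 10.0, mean=0.05, sd=0.00033),
    c6_data=d, fixed={"c2": 0.01, "c3": 0.001, "c4": 0.1, "c5": 0.05})
out = pba.propagate_pba(model, n_slices=50, method="grid", g=21)
print("expected residence time interval:", out.expectation_interval())
# expected residence time interval: (22.126302570212758, inf)
print("CDF bounds at y=22.0:", out.cdf_bounds(22.0))
# CDF bounds at y=22.0: (0.0, 0.04879999999999993)
print("CDF bounds at y=23.0:", out.cdf_bounds(23.0))
# CDF bounds at y=23.0: (0.9339999999999624, 0.9999999999999551)
```

Reading the output: any distribution of the two rates consistent with
the stated means and SDs produces an outcome CDF lying between the two
staircases, so at most 4.88% of cohorts can have a residence time below
22.0 and at least 93.4% must lie below 23.0.  The infinite upper
expectation is honest, not a bug: the stated support of the exit rate
c6 includes 0, and a cohort with no exit from state S3 resides there
forever; a conservative outer discretization must keep that corner.

The same pipeline is scriptable from a shell:

```sh
pba fixtures -o configs            # writes example YAML configs
pba propagate -c configs/case1.yaml -o results/case1
pba decide intervals.csv --rule hurwicz --alpha 0.5 -o report.json
```

## Layout

| module | contents |
| --- | --- |
| `pba.minimal`, `pba.bounding`, `pba.pbox` | summary-statistic records, bounding functions, p-box constructors, quasi-inverse, validity/enclosure checks |
| `pba.slicing` | outer discretization, hyperrectangle enumeration |
| `pba.propagation` | black-box model manifest, per-box optimizers, outcome p-boxes, mixed Monte Carlo propagation |
| `pba.decision` | expected-value intervals and the four comparison rules |
| `pba.cohort` | four-state residence model, CEA Markov engine, INMB |
| `pba.fixtures` | LP bound oracle, consistent-distribution generator, toy models |
| `pba.io`, `pba.config`, `pba.cli` | delimited-text staircases/records, YAML configs, `pba` command |

See `docs/methods.md` for the modelling conventions, numerical choices
and known limitations.
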