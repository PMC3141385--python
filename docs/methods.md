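# Methods

## Model structure and assumptions

The engine is a first-order (individual-level) Monte-Carlo Markov model with
annual cycles over a 10-year horizon. Four mutually exclusive living states —
diagnosed post-menopausal osteoporosis (PMO), post-vertebral, post-hip and
post-wrist fracture — plus absorbing death. Within each cycle events happen
in a fixed order: protection status → independent per-site fracture draws →
state update → death draw → ageing; costs attach at the end of the cycle and
are discounted with the end-of-cycle factor `(1+r)^(-c)`. There is no
half-cycle correction, no treatment switching, and no QALY computation
(effectiveness is measured as the proportions of fractured women and of
premature deaths, following French evaluation practice for this model
class).

Key transition rules:

* **Fracture risk.** `p = base(age, site) × RR × m`, capped at 1. `base` is a
  piecewise-constant age-band table (5-year bands from 50, open-ended above
  84). In the PMO state the baseline prior-fracture RR applies (when the
  woman entered with a fracture history); a post-fracture state RR *replaces*
  it rather than multiplying, because the state already encodes the worst
  history. The protective multiplier `m < 1` applies only while protected.
* **Missing cells.** The source evidence leaves the post-hip wrist RR and
  three treatment cells undefined. Setting them to 1.0 would create
  implausible discontinuities (a woman would become *safer* by fracturing),
  so they fall back to the nearest printed value: the baseline
  any-prior-fracture RR for risks, the baseline treatment multiplier for
  efficacy. Both are ordinary parameter-file entries and can be overridden.
* **Severity.** When several sites fracture in one year the state moves to
  the most severe event (hip > vertebral > wrist); all events are tallied
  and costed individually.
* **Vertebral split.** Every vertebral event counts in the vertebral tally
  and updates the state, but only the 23 % flagged symptomatic are costed
  and carry excess mortality. Because published "clinical fracture" counts
  are ambiguous about morphometric events, results report both the
  all-vertebral and the symptomatic-only tallies.
* **Death.** Baseline probability from the life table at current age, times
  the excess multiplier when a hip or symptomatic vertebral fracture
  occurred within the (1-year) excess window. Deaths drawn under an active
  multiplier are "premature" (fracture-related).

## Persistence and residual protection

`P(T) = 1 − b·ln(T)` with `b = 0.196`, clamped to 1 for T ≤ 1 month and to
the 20 % floor from 60 months onward (the floor mass represents women who
never discontinue within the horizon). `y(T) = a·e^(kT)` months of total
protection, `a = 13.5`, `k = 0.048`, with `y(0) = 0` imposed piecewise (the
exponential alone would grant 13.5 protected months to a woman who never
started). The published table was fit on weekly-regimen data; monthly
regimens are not modelled separately.

The two curves combine into the cohort protected proportion
`π(m) = P(min(m, T*(m)))` with `T*(m) = ln(m/a)/k`: whoever is still treated
at month m is protected, and whoever stopped after at least `T*(m)` months is
still inside her residual window. Since `y(T) ≥ 13.5` for every initiator,
π(m) = 1 through the first year; π(120) = 0.252. The microsimulation instead
samples one discontinuation time per woman by inverse transform
(`u < 0.20 → never; else T = exp((1−u)/b)`), which reproduces π(m) exactly in
distribution — the closed form is kept as the oracle and the two are tested
against each other at 10⁵ draws.

Drug exposure in the real-world arm is months-on-drug within the cycle / 12
(per woman); the ideal arm accrues a full year per cycle while alive; the
no-treatment arm accrues none. The cohort-level form (12-point mean of P over
the cycle's months, end-of-month convention: 0.674 in cycle 1) is retained
for deterministic checks. A persistence *uplift* λ mixes the curve toward
ideal, `P_λ = P + λ(1−P)`, and is the x-axis generator of the persistence
sweep (the axis itself is the 1-year persistence `P_λ(12)` in percent, with
the cost slope fitted by least squares and quoted per 10 points).

## Costs

Euros 2010 throughout; no inflation or currency adjustment. Fracture
management costs (hip €11,419, symptomatic vertebral €5,872, wrist €3,305)
are charged once, in full, at the event cycle — they already bundle
hospitalisation and rehabilitation. The hospitalisation component comes from
a DRG (disease-related-group) weighted average: Σ(stays × unit cost)/Σ stays.
The package ships synthetic DRG fixtures exercising that method; the
vertebral fixture decomposes the printed national aggregate exactly
(26,490 stays, €93,325,278 → €3,523/stay), while the hip and wrist fixtures
reproduce the printed stay counts and unit averages (the printed hip/wrist
aggregates are internally inconsistent with their own unit averages and are
not reproduced). The 12-week pack price (€52.23 generic base case, €87.46
branded sensitivity) converts to an annual cost via ×52/12; a 365.25-day
convention differs by <0.4 % and is selectable. A woman alive at cycle start
accrues that cycle's drug cost even if she dies during the cycle. Discount
rate 5 %/year (0 % sensitivity).

## Synthetic inputs and what they imply

Three inputs of the original analysis are not printed anywhere and are
replaced by explicit synthetic stand-ins, all flagged as such in code:

* **Population**: ages truncated-normal(70.5, 9.7²) on [50, 100], prior
  fracture Bernoulli(0.597). (The source reports both 70.5 and 71.1 as mean
  ages; the generator targets 70.5 and lands near 71 after truncation.)
* **Life table**: Gompertz `q(age) = min(1, s·e^(g·age))` anchored at
  q(70) = 0.012 and doubling every 8 years, terminal q(110) = 1. These
  anchors are round, demographically plausible values for elderly French
  women — not estimates of the 2004 national rates.
* **Excess mortality**: ×2.5 for one year after hip, ×2.0 after symptomatic
  vertebral fracture, no excess after wrist.

Consequently the *relative* structure of the results (arm orderings, fracture
ratios, dominance or its absence) is meaningful, while absolute counts of
deaths and euro totals shift with these stand-ins and should not be read as
replications of the published absolute figures. Passing tests demonstrate
internal correctness and agreement with the printed closed-form anchors, not
calibration to French vital statistics.

## Numerical and design choices

* Vectorized engine, one `numpy` PCG stream per run with a fixed draw order
  (discontinuation uniforms, then per-cycle site/symptomatic/death
  uniforms for the full cohort). Identical (seed, parameters) give identical
  results; equal seeds across arms give common-random-number coupling, which
  the null-efficacy identity test exploits.
* `cohort_expectation` propagates exact state probabilities (enumerating the
  2³ event patterns × symptomatic split per state) for reduced instances
  (≤4 cycles, single start age, 1-year excess window) and is the 3-SE
  convergence oracle for the engine at n = 200,000.
* Probabilities are capped at 1 after multiplication; degenerate inputs
  (q ≡ 1, zero risks, n = 1) are covered by tests of the cycle ordering.
* Report rounding: euros to the nearest integer, proportions to 3 decimals.

## Known limitations and a reproducibility finding

With the validated parameters this package reproduces the published
*fracture* outcomes closely (clinical-fracture ratios vs no treatment: 0.82
real-world and 0.62 ideal, against 0.819 and 0.607 published), and
real-world persistence dominates no treatment. It does **not** reproduce the
published dominance of ideal over real-world persistence: at €226.33/year
the ideal arm's incremental discounted drug cost (≈ +€1,090/patient) exceeds
its incremental fracture saving (≈ −€740), making improved persistence
cost-effective (≈ €5,000 per fractured woman avoided) but not cost-saving,
and the persistence→cost slope a net cost rather than a saving. The
published tables cannot all be satisfied simultaneously: their own outcome
counts priced at their own fracture costs match their no-treatment cost
column almost exactly (€4,447 vs €4,428 undiscounted per patient), yet
their ideal-arm totals imply only ~4 person-years of drug cost for 10 years
of full persistence at the stated price. The headline €270/patient and
€30.5M/year figures are therefore handled as published inputs to the
extrapolation arithmetic, alongside the package's own measured difference.
Other limitations: indirect and transport costs excluded, ambulatory costs
of morphometric fractures ignored, no probabilistic sensitivity analysis
beyond seed variation, and no re-fitting of the persistence curve to new
data (b = 0.196 is an input, not an estimate).
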