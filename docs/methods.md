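# Methods

## Decision problem and model structure

The package evaluates three first-line strategies for advanced
hepatocellular carcinoma (BCLC stage C, Child-Pugh A/B cirrhosis) —
full-dose sorafenib, dose-adjusted sorafenib, and transarterial
chemoembolization (TACE) — with a discrete-time Markov cohort model over
four health states:

1. compensated cirrhosis without tumour progression (all patients start
   here and receive active treatment),
2. compensated cirrhosis with progression (mRECIST; no further active
   treatment),
3. decompensated cirrhosis (Child-Pugh C; terminal, no further active
   treatment),
4. death (absorbing).

Cycles are one month; the horizon is 24 cycles, matching the short
survival of the population.  From the progression-free state the
competing monthly exits (death, progression, decompensation, plus an
optional additive background mortality, default 0) combine **additively**
on the probability scale, with a validation error if they sum past 1
(base-case sums peak near 0.33).  Progressed patients either die or stay:
the model has no progression-to-decompensation transition, a structural
assumption reflecting that post-progression mortality is the only exit
rate reported for that state.  Decompensated patients likewise die or
stay.

## Parameter derivation

Published survival medians convert to monthly probabilities by the
declining exponential approximation of life expectancy (DEALE): with
median *m* months, hazard `mu = ln2/m` and `p = 1 - exp(-mu)`.  This
conversion reproduces all fourteen published "derived monthly rate"
table cells to the printed two decimals, which is the evidence that it is
the conversion the original analysis used.  `prob_to_median` is its exact
inverse.

Study-level proportions pool on the Freeman-Tukey double-arcsine scale,
`t = asin sqrt(x/(n+1)) + asin sqrt((x+1)/(n+1))`, variance `1/(n+0.5)`,
which stabilises the binomial variance and admits zero-event studies.
Between-study variance uses the DerSimonian-Laird estimator (the standard
when a "random-effects model" is named without qualification), and the
pooled value and its normal-theory interval are returned to the
proportion scale with **Miller's back-transformation**, using the
harmonic mean of the study sizes as the effective n.  The implementation
agrees with R `metafor` (`escalc(measure="PFT")` + `rma(method="DL")` +
`transf.ipft.hm`) to 1e-10 on a frozen five-study set.  Per-study
intervals use the Wilson score method (never below 0 or above 1); the
normal quantile is computed, not the rounded 1.96.  Note the published
pooled probabilities themselves (11.5%, 6.5%, 19.0%, 11.2%) enter the
scenario files as constants: the per-study counts behind them were never
printed.

## Rewards, counting, and discounting

Per cycle *t* with occupancy weight *w* and discount *d(t)*:

- life-months += `sum(w[alive]) * d(t)`
- QALYs += `sum(w[s] * u[s]) / 12 * d(t)`
- cost += `(sum(w[s] * c[s]) + w[progression-free] * treatment(t)) * d(t)`

Three counting conventions are implemented — `begin` (pre-transition
occupancy), `end` (post-transition), `half` (their mean, the half-cycle
correction) — together with two discount mappings: the textbook
`d(t) = (1+r)^(-t/12)` for an annual rate over monthly cycles, and a
per-cycle form `d(t) = (1+r)^(-t)` in which the annual rate compounds
every cycle, plus a switch for whether the first cycle is discounted.
Class defaults are the textbook choices (`begin`, annual, first cycle
discounted); life-months are discounted with the same stream as QALYs
and costs.

**Convention calibration.**  The original analysis (built in a
commercial tree package) does not state its conventions, so
`analysis/01_convention_calibration.py` runs the base case under all
twelve combinations against the published totals
(`results/convention_calibration.csv`).  Half-cycle counting with the
per-cycle discount form and an undiscounted first cycle reproduces all
six published LYG/QALY values within +1.3% (the next-best grid point is
off by 2.7%, and the textbook convention by 21-33%, so the published
analysis evidently discounted each monthly cycle at the nominal annual
rate).  The shipped scenario files therefore set
`cycle_counting: half`, `discount_per_cycle: true`, `discount_offset: 1`.
Under this convention lifetime costs land within -6.0% to +10.7% of the
published figures; no grid point does better on costs without giving up
the effectiveness match (the cost-optimal and effectiveness-optimal
settings differ by exactly one uniform factor of 1.03), so the residual
cost gap reflects unpublished structural detail of the original model,
not a convention choice.  In particular the published China cost
ordering (dose-adjusted $153 cheaper than TACE) is finer than the
reproduction can resolve.

## Costs and utilities

All costs are 2016 USD, healthcare-system perspective.  Treatment cost
accrues only in the progression-free state: sorafenib strategies pay the
full monthly drug price for cycles 1-3 and the assistance-programme
price from cycle 4 (both countries, exactly as published — including the
USA's $1.2/month post-assistance price, used verbatim); TACE is priced
per session with a configurable `sessions_per_cycle` factor, default one
session per monthly cycle while progression-free (the reading consistent
with a monthly cost table; no retreatment schedule was published).  The
compensated-state management cost stacks on top of treatment cost;
progressed and decompensated states carry only their own monthly costs;
death costs nothing.  Utilities (QALY-weights per year of occupancy) are
0.76 / 0.68 / 0.57 / 0 by state.

## Incremental metrics and NMB scales

Strategies are ranked by QALYs; adjacent pairs (and each strategy against
the least effective) are compared as `ICER = deltaC / deltaE` in dollars
per QALY-year, with negative ratios reported alongside dominance flags —
the published convention.  `NMB = WTP x E - C`; the decision rules are
dual: NMB(A) > NMB(B) iff `(WTP - ICER_AB) x deltaE > 0`.  Extended
dominance pruning is not applied (all pairwise ratios are reported, as
published).

The deterministic sensitivity and acceptability analyses expose an
`effect_scale` argument: `ly_months` (default), `qaly_months`, or
`qaly_years`.  The default measures effectiveness in **discounted
life-months**, because the published threshold results are mutually
consistent only on that scale: with it, the full-dose drug-price
crossover lands at $13,356 (published $13,973.90), the TACE mortality
crossover at the $15,200.8 price point lands at 12.42%/month (published
12.3%), and the deterministic full-dose-vs-TACE tie in China sits near
$10,100 per life-month (the published acceptability crossing is
$10,473) — whereas on the dollars-per-QALY-year scale none of those
crossovers exists at all, because at the China threshold TACE's NMB
exceeds full-dose sorafenib's at base case.  The tabular ICER/NMB
functions remain on the standard QALY-year scale.  Tornado bars report
the spread of the frontier (max-NMB) strategy by default, switchable to a
single strategy's own NMB; ties in bar width break by parameter id so
the ordering is input-order invariant.

## Probabilistic sensitivity analysis

Each parameter with a range receives a distribution: gamma for costs,
beta for probabilities and utilities, parameterised by moments with mean
equal to the base value and standard deviation `(high - low)/(2 x 1.959964)`
— the range treated as a 95% interval (the original parameterisation is
unpublished; treating 50-200% cost ranges as hard uniform bounds is the
selectable alternative interpretation but concentrates far more mass at
extreme costs).  Degenerate ranges become point masses.  Parameters are
sampled independently; ids shared between strategies (the sorafenib
post-progression mortality and decompensation rate, the decompensated
mortality) are drawn once per replicate.  Draws whose progression-free
exits sum past 1 are renormalised and counted (none occur in 10,000
draws at the shipped ranges).  Replicates run through the same cohort
engine in one vectorised batch; 10,000 draws for both countries take
about two seconds on one core.

CEAC probabilities are the fraction of replicates in which a strategy
has the strictly highest NMB, ties split equally; the default WTP grid
is $0-$100,000 in $500 steps.  Median ICERs and central 95% intervals
against the dose-adjusted reference are computed per draw, excluding and
counting draws with |deltaE| below 1e-9 QALY.

A caution that the test suite makes explicit: with distributions centred
on the base case, the PSA *mean* outcome is not the base-case outcome —
the model is nonlinear, so propagation adds a convexity offset (about
+2% on cost, +5% on QALY here) that no sample size removes.  PSA means
are therefore validated by self-consistency between independent runs at
different sample sizes, not against the deterministic base case.

## Synthetic data

`synthetic.gen_study_set` draws per-study event counts with
heterogeneity injected on the arcsine scale, where the pooling model is
correctly specified — parameter-recovery tests therefore test the
estimator, not model misfit.  `gen_survival_cohort` draws exponential
event times, matching the constant-hazard assumption behind the DEALE
conversion.  `gen_scenario` produces random, always-valid three-strategy
scenarios for fuzzing the engine, the decision metrics, and the
crossover search.  All generators are seed-deterministic.  What the
generators do **not** emulate: non-exponential (e.g. cure-fraction or
heavy-censoring) survival, correlated parameters, publication bias in
study sets, or real per-study extraction tables — so passing
recovery tests show estimator correctness under the model's own
assumptions, not robustness to their violation.

## Numerical choices

- Crossover search: Brent bisection between the range ends, relative
  tolerance 1e-6; `None` when the NMB gap has no sign change; identical
  curves (gap identically zero at both ends) also return `None`.
- Two-way grids default to 101x101 evaluated as one vectorised batch.
- Occupancy conservation is maintained to 1e-10 per cycle; validation
  tolerances on probability sums are 1e-12.
- Miller back-transformation clamps to [0, 1] outside the attainable
  range of the transform at the effective sample size.
- Test problem sizes: the cohort-vs-simulation oracle uses 100,000
  random walks on the base scenario and 30,000 walks on each of 100
  random scenarios (with a 99%-within-3-SE criterion, since 900
  z-comparisons make a few 3-SE exceedances expected); PSA properties
  are exercised at 2,000/10,000/20,000 draws.

## Known limitations

- The reproduction matches published effectiveness to ~1% but lifetime
  costs only to ~10%; conclusions that hinge on sub-$200 cost
  differences between strategies (the published China TACE vs
  dose-adjusted ordering) are below its resolution.
- Background age-specific mortality defaults to zero; at age 60 its
  monthly magnitude is negligible against disease mortality, but the
  hook is an additive hazard, not a life table.
- No treatment crossover, second-line therapy, or time-varying
  transition probabilities beyond the price switch; individual-level
  simulation exists only as a test oracle.
- Currency is fixed 2016 USD; no inflation or currency conversion.
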