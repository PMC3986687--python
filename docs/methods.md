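# Methods

## Model

`burdensim` predicts the population health burden of a regulated
engineering technology by resampling its own occurrence history.  The
chain is:

1. **Rate.** `lambda = bias * (n_i + n_m / r) / T` occurrences per year,
   from `n_i` incidents and `n_m` near misses over `T` observed years.
   The rate is assumed constant over the prediction horizon (a
   homogeneous Poisson process); a time-dependent `lambda(t)` is out of
   scope.
2. **Occurrences.** Per iteration, `N ~ Poisson(lambda * horizon)`.
   Each occurrence independently draws a causal category (SIM1, SIM2,
   SIM3, RCNE) from the empirical cause distribution and a victim count
   from a discrete uniform on `{0, ..., M}`.  Victimless occurrences
   contribute zero burden but are counted.
3. **Victims.** Each victim draws an age (resampled from the observed
   victim ages; uniform on a configured range if none are available), an
   injury count from the empirical 1..K distribution, and that many
   injury types **with replacement** from the empirical injury-type
   distribution.  Duplicate draws are each scored — an accepted
   computational simplification of field practice, where an inspector
   records each applicable type once.
4. **Scoring.** `DALY = st_weight * st_duration + lt_weight *
   fraction_long_term * remaining_life`.  A fatal draw discards the
   victim's other injuries and scores the full remaining life
   expectancy.  No age-weighting or time-discounting is applied.
5. **Reporting.** Per-iteration totals are accumulated into the
   occurrence's cause bucket (totals equal the bucket sum exactly, by
   construction).  Summaries report the arithmetic mean, empirical
   percentiles (order statistics with linear interpolation, default grid
   5/25/50/75/95%), per-cause means, and DALYs per million exposed
   persons per year (`mean / horizon / (population / 1e6)`), dividing by
   the whole configured exposed population.

The cause draw is independent of severity and victim count: the model
couples them only through the occurrence loop, so the per-cause burden
shares equal the cause probabilities in expectation.

A second-order layer separates *uncertainty* from *variability*: the
outer loop draws the reporting-bias multiplier from a point, uniform or
triangular distribution (support at or above 1), rescales the rate from
its count ingredients, and reruns the inner loop.  A point-mass bias
with one outer draw reduces bit-exactly to the first-order model.

## Parameters

| parameter | units | default | rationale |
|---|---|---|---|
| `r` (near-miss ratio) | — | 1 | conservative: every near miss counts fully toward the rate |
| `bias` | — | 1 | no unreported occurrences; field lore of "ten unreported per reported" corresponds to 10–11, exposed via the bias distribution |
| `T` | years | from data | observation span of the records |
| `horizon` | years | 1 | one-year-ahead prediction |
| `M` (max victims) | persons | 6 | a typical elevator carries zero to six riders; presets may use the historical maximum (3) instead — both readings are legitimate and configurable |
| `K` (max injuries/victim) | — | 4 | victims have sustained up to four injuries |
| `pool_mass` | probability | 0.01 | reserved for never-observed injury types, split equally among them: rare but reachable |
| `population` | persons | 13.4e6 | exposed population (Ontario), for per-million normalisation |
| remaining life | years | constant 44.4 | median remaining life expectancy, gender-averaged; a life table (age, remaining_years) with linear interpolation and end clamping may be supplied instead |
| `iterations` | — | 10,000 | inner Monte Carlo sample size |

## Disability catalogue

The packaged 15-row catalogue adapts AIHW / GBD disability weights to a
regulator's injury vocabulary (concussion via intracranial injuries,
sprains, poisoning, heart attack via rheumatic heart disease +
heart failure, ...).  High-incidence minor types with no burden-of-disease
counterpart (aches, bruises, swelling) carry nominal weights < 0.02 and
~1-week durations.  Two sentinel rows close the algebra: `Fatal injury`
(0, 0, 1, 1), whose DALY is the remaining life expectancy exactly, and
`No Injury` (all zeros), which lets injury-free outcomes flow through
the same machinery.  The spinal-injury row ships with a nonzero
short-term weight but zero short-term duration, as printed in its
source; the acute term is computationally inert and is implemented as
printed.  The provenance column is carried as free text and never used
in computation.

## Synthetic data generator

`synthetic.generate` emulates the statistical structure the simulator
assumes — nothing more: Poisson occurrence counts over the span,
Bernoulli incident/near-miss split, i.i.d. categorical causes, uniform
dates, 0..M victims per incident, 1..K injuries per victim from a skewed
categorical, uniform ages.  `elevator_preset()` calibrates the expected
counts to the published elevating-device history (2638 incidents, 1028
near misses, 4.6 years, expected injury-free incident fraction
138/2638 via an explicit victim-count categorical), but its injury-type
and causal-category vectors are **documented synthetic surrogates** —
the source distributions were only published graphically — skewed the
way elevator data are: sprains and bruises dominate, fatality
probability ~1.3e-3.  Passing recovery tests therefore demonstrates
correctness of the fitting/simulation machinery under the model's own
assumptions, not agreement with any real sector's figures; real
histories have seasonality, device covariates and reporting drift the
generator deliberately omits.

## Numerical and design choices

- **RNG policy.** One root seed; every (outer, inner) iteration gets an
  independent child stream via `SeedSequence((seed, outer, inner))`, so
  reruns are bit-identical and results do not depend on execution order.
- **Vectorised inner loop.** Each iteration flattens occurrences ->
  victims -> injuries into numpy arrays and folds injury DALYs back per
  victim with segmented reductions; the scalar `sample_victim` is the
  readable reference path and is held to the same distributions by test.
- **Order-invariant summaries.** Iteration totals are sorted before
  averaging so summaries are exactly invariant to iteration order
  despite floating-point non-associativity.
- **Pooling estimator.** The pooled injury fit intentionally biases
  unobserved types upward (and observed ones down by `1 - pool_mass`);
  parameter-recovery tests therefore use `pool_mass = 0`, and the
  pooling arithmetic is tested exactly on fixtures.
- **Degenerate inputs.** Zero rate yields all-zero burden; `M = 0`
  yields victimless occurrences only; empty datasets raise fit errors
  rather than returning silent defaults.
- **Problem sizes in tests.**  Closed-form oracle checks use 4,000–10,000
  iterations at rates of 20–80/yr (3-standard-error acceptance);
  recovery tests use ~5,000-occurrence synthetic histories (3 binomial
  standard errors); the monotonicity grid uses 3,000–4,000 iterations
  per point, where the expected separation is many times the Monte
  Carlo error.

## Limitations

- Constant rate: no seasonality, trend, or nonhomogeneous Poisson
  behaviour.
- Every member of the exposed population is treated as equally exposed;
  no device-level or person-level heterogeneity.
- Cause, victim count and severity are mutually independent given an
  occurrence.
- DALYs are undiscounted and un-age-weighted; disability weights are
  proxies adapted from disease studies and carry their documented
  caveats.
- The victim-count and injuries-per-victim distributions are bounded
  (`M`, `K`); mass catastrophes outside the historical envelope are not
  represented.
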