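# Methods

## Problem and scope

Multicenter randomized trials frequently recruit slower than planned, and
poor recruitment is the leading cause of premature discontinuation. The
practical monitoring questions are: given `m` patients randomized after
`t` months against a target of `n`, how long will recruitment take, with
what uncertainty, and what is the risk of finishing after the anticipated
time `T`? This package provides (i) a synthetic generator for portfolios
of trials with the statistical structure those questions presuppose,
(ii) descriptive analyses of recruitment trajectories, (iii) a Bayesian
accrual prediction model with a constant-rate frequentist comparator, and
(iv) a landmark validation engine that scores both models against
realized recruitment times.

## The accrual model

Waiting times between successive randomizations are modelled as i.i.d.
exponential with unknown mean θ (months per patient). The prior on θ is
inverse-gamma,

    θ ~ InvGamma(shape = P·n, scale = P·T),

where `n` is the planned sample size, `T` the anticipated recruitment
time in months, and `P ∈ [0, 1]` a prior-confidence weight: the planning
assumptions are granted the evidential weight of a fraction `P` of the
full planned trial. Observing `m` randomizations in `t` months (the sum
of the observed waiting times is `t`), conjugacy gives

    θ | data ~ InvGamma(P·n + m, P·T + t).

`P = 0` is the non-informative limit (scale-invariant prior ∝ 1/θ),
proper once `m ≥ 1`. Requesting a non-informative posterior with `m = 0`
is an error rather than a silent fallback.

Predictions are posterior-predictive by direct Monte-Carlo: draw θ from
the posterior, then

* **completion time**: residual time to recruit the remaining `r`
  patients is Gamma(r, θ); `T_pred = t + Gamma(r, θ)`;
* **accrual count**: additional patients over a horizon `h − t` is
  Poisson((h − t)/θ).

Because the posterior is conjugate, no Markov chain is needed; the
default draw count is 50,000. The point estimate is the predictive
median (the completion-time distribution is right-skewed; the mean is
also reported), and intervals are equal-tailed at a default 95% level.
The risk of accrual failure is

    P_late = Pr(T_pred > T | data),

estimated as the fraction of predictive draws exceeding `T`. A trial is
flagged as slow-accruing when `T` lies strictly below the lower interval
bound of `T_pred`.

**Constant-rate comparator.** The frequentist alternative estimates the
rate as `m/t` and extrapolates: point completion time `n·t/m`. Its
interval propagates the exact (gamma-inversion) Poisson confidence
interval for a rate observed as `m` events in exposure `t`; the lower
rate bound maps to the upper time bound.

**Site-activation-aware variant.** When activation dates are available,
exposure is re-expressed in site-months `s(t) = Σ_j max(0, t − a_j)`
(activation offsets `a_j`), θ becomes the mean waiting time per
site-month, with posterior InvGamma(P·n + m, P·s(T) + s(t)), and
predicted residual *exposure* Gamma(r, θ) is mapped back to calendar time
by inverting the piecewise-linear exposure function of the schedule.
With all sites active from day 0 this reduces exactly to the single-rate
model with `t` replaced by `k·t`.

## Synthetic portfolios

The generator emulates what the analyses assume about real multicenter
trials: each site recruits as a Poisson process at a constant base rate
drawn from a gamma distribution (cross-site heterogeneity), sites after
the first activate with exponential lags, and an optional seasonal
modulation thins the dominating homogeneous process with acceptance
probability proportional to `1 + A·cos(2π(month − phase)/12)`. Thinning
keeps the amplitude-0 case exactly exponential and provides a simple
analytic oracle for the seasonal peak. Defaults describe a mixed
portfolio of investigator-initiated trials: lognormal recruitment
targets (median 150, σ = 0.7, floor 20), 1–20 sites, mean one patient
per site-month (gamma shape 2), mean activation lag 2 months, anticipated
recruitment time equal to the rate-implied duration `target / Σ rates`,
recruitment targets inflated 10% above the statistical sample size, and
25% of trials cut off at half their implied duration — the
poor-recruitment discontinuation arm, roughly matching the observation
that about a quarter of trials discontinue prematurely with poor
recruitment the leading reason. These defaults are declared placeholders
for a realistic mixed portfolio; they are not calibrated to any real
trial database.

Per-trial random streams derive from `SeedSequence((seed, trial_index))`,
so portfolios reproduce byte-identically across runs and platforms and
any single trial can be re-simulated in isolation. Event times are
written as ISO dates (continuous month offsets floored to whole days);
same-day randomizations collapse into one trajectory step.

What the generator does *not* emulate: informative site closure,
consent/refusal dynamics, rate drift within a site (beyond seasonality),
country effects, and administrative start-up gaps. Tests passing on
these portfolios therefore certify the statistical machinery under the
model's own assumptions — constant per-site rates above all — not
performance on real recruitment data, where rate drift and ramp-up are
common.

## Conventions and numerical choices

* A month is 365.25/12 = 30.4375 days everywhere.
* Trial time origin is the date of the first randomized patient; an
  activation origin (earliest recorded site activation) is available as
  an option and falls back to the first event when no usable activation
  date exists.
* Time-based landmarks count events in the half-open window `[0, t)`
  days; proportion-based landmarks locate the first step reaching
  `ceil(p·target)` patients.
* Completion classification: a stated discontinuation reason always
  wins; otherwise a trial is discontinued "for unknown reason" when the
  achieved count falls below 90% (strict) of the reference size — the
  statistical sample size when recorded, else the recruitment target.
  The 80% sensitivity rule is inclusive ("80% or less").
* Dates are strict ISO-8601; malformed rows are reported with row
  numbers and the offending value, and a missing mandatory column is a
  schema error.
* Validation truth: "true" recruitment time is the time to the last
  randomized patient, and predictions target the achieved final count,
  so discontinued trials are scored on a quantity they realized rather
  than a target they never reached. Landmarks at or beyond the end of
  recruitment are skipped (hindsight) and tallied.
* Model seeds inside the validation engine derive from
  `SeedSequence((seed, trial_index, landmark_index, model_index))`, so
  every row is exactly reproducible from (portfolio, seed, config).

## Descriptive analyses

* **Seasonal profile**: per calendar month, observed accrual is compared
  with the expectation under uniform accrual over each trial's active
  window (its day-exposure to that month); the index is their ratio
  (exposure-weighted mean 1 by construction). Significance uses a
  rotation permutation: each trial's calendar anchor is shifted by an
  independent uniform 0–11 month offset, preserving within-trial
  structure while destroying calendar alignment; the statistic is a
  chi-square-style deviation of observed from expected.
* **Early-slope association**: Spearman correlation between the fraction
  of target recruited within the first `w` months (default 3) and the
  final fraction achieved, with a 1000-resample percentile bootstrap
  interval; trials observed for less than `w` months are excluded.
* **Site readiness**: trials split by whether > 80% of sites activated
  within one month of trial start; mean proportion-of-target
  trajectories are compared on a common monthly grid.
* **Pattern checks**: six classical recruitment patterns (early speed vs
  attainment, early vs subsequent accrual, the month-2/month-1
  acceleration ratio, 2-month counts vs final accrual, the <30%-at-10-
  months failure rule, and absence of marked late acceleration). Rank
  (Spearman) correlation is used throughout — accrual counts are
  heavily skewed. Checks on empty strata report "not evaluable", never
  a number.

"Marked acceleration" has no canonical definition; this package flags a
trial when the OLS slope of monthly counts (dropping the censored final
month bin) is positive and exceeds **three** times its standard error
and the mean rate from month 12 onward exceeds 1.5× the months-1–3 mean.
The 3-SE threshold keeps the false-flag probability per constant-rate
trial well below 1%, so a constant-rate portfolio of realistic size
flags zero trials; a 2-SE threshold would flag spurious accelerations in
roughly one constant-rate portfolio in five.

With the first-randomization origin the first month always contains at
least one patient, so the acceleration-ratio exclusion ("month-1 count
zero") can only trigger under the activation origin; the guard is kept
for that path.

## Calibration experiments

`accrual.calibration` simulates recruitment from the model's own
generative assumptions (θ drawn from the informative prior, single-site
exponential waits) and measures frequency properties end-to-end:

* **Interval coverage**: with a matched prior the posterior-predictive
  interval for total recruitment time is exactly calibrated, so its
  empirical coverage at the 50%-accrual landmark over 1000 trials should
  equal the nominal 95% up to binomial noise (SE ≈ 0.7 pp). This is the
  quantity `scripts/acceptance.py` recomputes.
* **P_late calibration**: trials binned by predicted P_late should be
  late with frequency equal to the bin mean; the test uses
  Bonferroni-simultaneous binomial bands across bins, since requiring
  every unadjusted 95% band simultaneously would reject an exactly
  calibrated model about a third of the time.
* **Early-landmark comparison**: on prior-consistent portfolios the
  informative Bayesian model should beat the constant-rate extrapolation
  at the month-1 landmark, where `m/t` rests on a handful of events; the
  experiment measures the fraction of 100 portfolio replicates (20
  trials each) in which its median %Rbias is lower.

Problem sizes (1000 coverage trials, 500 calibration trials, 100
comparison replicates, 50,000 predictive draws for coverage and 2000–
5000 elsewhere) are chosen so each experiment resolves its target to
well under the asserted tolerance while the whole suite runs in minutes
on one CPU.

## Known limitations

* The constant-rate assumption is shared by generator and model in all
  calibration experiments; none of the reported numbers measure
  robustness to ramp-up or rate drift.
* The prior hyperparameterization (how P scales shape vs scale) follows
  the standard conjugate accrual formulation; other published accrual
  tools may parameterize prior confidence differently, so P values are
  not directly transferable.
* The seasonal permutation test rotates whole-month offsets and so has
  reduced power against sub-monthly structure.
* Discontinued-trial validation scores predictions of the achieved
  count; it does not attempt counterfactual time-to-target for trials
  that never reached it.
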