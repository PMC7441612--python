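# accrual

Tools for predicting and monitoring patient recruitment in randomized
clinical trials: a synthetic generator for multicenter recruitment data,
descriptive trajectory analyses, a conjugate Bayesian accrual prediction
model with a constant-rate frequentist comparator, and a landmark
validation engine that scores both models against realized recruitment
times.

The intended users are trial statisticians and methodologists who need
to answer, at planning time or at an interim look: *how long will
recruitment take, with what uncertainty, and what is the risk of
finishing late?*

## Model

Waiting times between randomizations are i.i.d. exponential with
unknown mean θ (months/patient). Planning assumptions — sample size *n*,
anticipated recruitment time *T*, confidence weight *P* ∈ [0, 1] — enter
through an inverse-gamma prior, and observing *m* patients in *t* months
gives the conjugate posterior

    θ ~ InvGamma(P·n, P·T)   →   θ | data ~ InvGamma(P·n + m, P·T + t).

Predictions integrate over θ by direct Monte-Carlo (default 50,000
draws): completion time `T_pred = t + Gamma(remaining, θ)`, accrual over
a horizon as a Poisson count. Reported are the predictive median, an
equal-tailed 95% interval, the risk of accrual failure
`P_late = Pr(T_pred > T | data)`, and a slow-accrual flag (*T* below the
interval's lower bound). The comparator extrapolates the constant rate
`m/t` with an exact Poisson-rate interval. A site-activation-aware
variant measures exposure in site-months and integrates the future
activation schedule. Prediction accuracy is scored with
`%Rbias = |Predicted − True| / True × 100`.

See `docs/methods.md` for assumptions, conventions, and limitations.

## Worked example

Simulate a 40-trial portfolio, validate both models at the default
landmark grid, and predict one trial interactively:

```
$ accrual simulate --out demo/data --seed 1 --n-trials 40
wrote 40 trials to demo/data
$ accrual validate --data demo/data --out demo/validation.csv --draws 10000 --seed 1
wrote 1305 rows to demo/validation.csv
```

Median %Rbias of the predicted completion time by model and time
landmark (months), from `demo/validation.csv`:

```
landmark_value        1.0   3.0   6.0   9.0   12.0
bayes_informative      6.0   8.9   4.5   3.5   2.9
bayes_noninformative  79.6  26.9  11.8   6.3   4.5
linear                71.1  25.6  11.5   7.3   5.9
```

At month 1 the informative prior (here well specified: the simulated
anticipated times equal the rate-implied durations) dominates the
data-only models, whose rate estimate rests on a handful of events; by
month 12 all three converge. Empirical 95%-interval coverage over all
rows: 0.95 (Bayes informative), 0.81 (non-informative), 0.66 (linear) —
the constant-rate interval ignores parameter uncertainty early on.

A single interim prediction (planned n = 200, anticipated T = 24 months,
prior weight 0.5, 50 patients after 5 months):

```
$ accrual predict --n 200 --t 24 --p 0.5 --recruited 50 --elapsed-months 5 \
    --draws 5000 --seed 1
{
  "posterior": {"shape": 150.0, "scale": 17.0},
  "point_months": 22.0,
  "interval": [18.6, 26.3],
  "p_late": 0.171,
  "slow_accrual": false
}
```

Read: the trial most likely completes around month 22, with a 17% risk
of overrunning its anticipated 24 months; accrual is not flagged as
slow.

`accrual describe` produces the descriptive report (seasonal profile,
early-slope association, site-readiness split, anticipated-vs-actual,
six classical pattern checks) and `accrual report` bundles everything
into one Markdown document with plots.

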