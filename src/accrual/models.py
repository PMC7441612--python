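"""Accrual prediction models.

The Bayesian model treats waiting times between successive randomizations
as i.i.d. exponential with unknown mean theta (months per patient). The
prior on theta is inverse-gamma with shape ``P * n`` and scale ``P * T``,
where ``n`` is the planned sample size, ``T`` the anticipated recruitment
time (months) and ``P`` in [0, 1] a prior-confidence weight: ``P`` is
roughly the fraction of the planned trial's worth of information granted
to the planning assumptions. Having observed ``m`` patients in ``t``
months, conjugacy gives the posterior

    theta | data ~ InvGamma(P * n + m,  P * T + t).

``P = 0`` is the non-informative limit (Jeffreys-type prior proportional
to 1/theta), proper as soon as one patient is observed.

Predictions integrate over theta by direct Monte-Carlo: draw theta from
the posterior, then the waiting-time sum (gamma) for completion time, or
a Poisson count for accrual over a horizon. The default draw count is
50,000. A frequentist comparator extrapolates a constant rate ``m / t``
with an exact Poisson-rate confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .trial_data import InterimState


@dataclass(frozen=True)
class AccrualPrior:
    """Planning assumptions: sample size ``n``, anticipated time ``T``
    (months), and prior confidence weight ``P`` (0 = non-informative)."""

    n: int
    T: float | None = None
    P: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("planned sample size n must be >= 1")
        if not 0 <= self.P <= 1:
            raise ValueError("prior weight P must lie in [0, 1]")
        if self.P > 0 and (self.T is None or self.T <= 0):
            raise ValueError("informative prior (P > 0) requires T > 0")


@dataclass(frozen=True)
class PosteriorState:
    """Inverse-gamma posterior over the mean waiting time theta
    (months/patient), with the interim data that produced it."""

    shape: float
    scale: float
    m: int
    t: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("posterior shape and scale must be positive")

    @property
    def mean_theta(self) -> float:
        """Posterior mean of theta; requires shape > 1."""
        if self.shape <= 1:
            return float("nan")
        return self.scale / (self.shape - 1.0)

    def sample_theta(self, draws: int, rng: np.random.Generator) -> np.ndarray:
        # InvGamma(a, b) = b / Gamma(a, 1)
        return self.scale / rng.standard_gamma(self.shape, size=draws)


@dataclass
class PredictionResult:
    """A posterior-predictive (or frequentist) prediction.

    ``point`` is the predictive median for Monte-Carlo results (robust to
    the heavy right tail of completion times); ``mean`` is also reported.
    ``interval`` is equal-tailed at ``level``.
    """

    kind: str  # completion_time | accrual_count
    point: float
    interval: tuple[float, float]
    level: float
    mean: float | None = None
    p_late: float | None = None
    draws: np.ndarray | None = None
    seed: int | None = None
    model: str = "bayes"

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not lo <= hi:
            raise ValueError("interval bounds out of order")
        if self.p_late is not None and not 0 <= self.p_late <= 1:
            raise ValueError("p_late must lie in [0, 1]")


def fit_posterior(prior: AccrualPrior, interim: InterimState) -> PosteriorState:
    """Conjugate update: shape = P*n + m, scale = P*T + t."""
    if prior.P == 0 and interim.m == 0:
        raise ValueError("posterior improper: non-informative prior with no events")
    if interim.t <= 0:
        raise ValueError("elapsed time t must be positive")
    shape = prior.P * prior.n + interim.m
    scale = prior.P * (prior.T or 0.0) + interim.t
    return PosteriorState(shape=shape, scale=scale, m=interim.m, t=interim.t)


def _summarize(
    draws: np.ndarray, kind: str, level: float, seed: int | None, model: str
) -> PredictionResult:
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return PredictionResult(
        kind=kind,
        point=float(np.median(draws)),
        mean=float(np.mean(draws)),
        interval=(float(lo), float(hi)),
        level=level,
        draws=draws,
        seed=seed,
        model=model,
    )


def predict_completion_time(
    post: PosteriorState,
    remaining: int,
    draws: int = 50_000,
    seed: int | None = None,
    level: float = 0.95,
) -> PredictionResult:
    """Posterior-predictive completion time T_pred = t + (time to recruit
    the remaining patients).

    Monte-Carlo scheme: theta ~ InvGamma(shape, scale); the residual time
    is the sum of ``remaining`` exponential waiting times, i.e.
    Gamma(remaining, theta).
    """
    if remaining < 0:
        raise ValueError("remaining must be non-negative")
    if remaining == 0:
        return PredictionResult(
            kind="completion_time",
            point=post.t,
            mean=post.t,
            interval=(post.t, post.t),
            level=level,
            draws=np.full(1, post.t),
            seed=seed,
        )
    rng = np.random.default_rng(seed)
    theta = post.sample_theta(draws, rng)
    residual = rng.standard_gamma(remaining, size=draws) * theta
    return _summarize(post.t + residual, "completion_time", level, seed, "bayes")


def predict_accrual(
    post: PosteriorState,
    horizon: float,
    draws: int = 50_000,
    seed: int | None = None,
    level: float = 0.95,
) -> PredictionResult:
    """Posterior-predictive total accrual at a future time ``horizon``
    (months from trial start): m plus a Poisson((horizon - t)/theta) count."""
    if horizon <= post.t:
        raise ValueError("horizon must exceed the elapsed time t")
    rng = np.random.default_rng(seed)
    theta = post.sample_theta(draws, rng)
    counts = rng.poisson((horizon - post.t) / theta)
    return _summarize(
        post.m + counts.astype(float), "accrual_count", level, seed, "bayes"
    )


def p_late(
    post: PosteriorState,
    remaining: int,
    T: float,
    draws: int = 50_000,
    seed: int | None = None,
) -> float:
    """Risk of accrual failure: Pr(T_pred > T | data), the fraction of
    posterior-predictive completion-time draws later than the anticipated
    completion time T."""
    if T <= 0:
        raise ValueError("anticipated time T must be positive")
    if remaining == 0:
        return float(post.t > T)
    pred = predict_completion_time(post, remaining, draws=draws, seed=seed)
    return float(np.mean(pred.draws > T))


def flag_slow_accrual(pred: PredictionResult, T: float) -> bool:
    """True when the anticipated completion time T lies strictly below the
    lower bound of the predicted completion-time interval."""
    if pred.kind != "completion_time":
        raise ValueError("slow-accrual flag applies to completion-time predictions")
    return T < pred.interval[0]


def linear_predict(
    interim: InterimState, n: int | None = None, level: float = 0.95
) -> PredictionResult:
    """Constant-rate comparator.

    The rate is estimated as m/t and the completion-time point estimate is
    n*t/m. The interval propagates the exact (gamma-inversion) Poisson
    confidence interval for a rate observed as m events in exposure t:
    a lower rate bound maps to an upper time bound.
    """
    if interim.m < 1:
        raise ValueError("rate inestimable: no events observed")
    if interim.t <= 0:
        raise ValueError("elapsed time t must be positive")
    n = interim.n if n is None else n
    if n < interim.m:
        raise ValueError("target n below observed count m")
    if n == interim.m:
        return PredictionResult(
            kind="completion_time",
            point=interim.t,
            mean=interim.t,
            interval=(interim.t, interim.t),
            level=level,
            model="linear",
        )
    alpha = (1.0 - level) / 2.0
    m, t = interim.m, interim.t
    remaining = n - m
    # exact Poisson-rate CI: [gamma.ppf(a/2, m), gamma.ppf(1-a/2, m+1)] / t
    rate_lo = stats.gamma.ppf(alpha, m) / t
    rate_hi = stats.gamma.ppf(1.0 - alpha, m + 1) / t
    point = n * t / m
    lo = t + remaining / rate_hi
    hi = t + remaining / rate_lo if rate_lo > 0 else float("inf")
    return PredictionResult(
        kind="completion_time",
        point=point,
        mean=point,
        interval=(lo, hi),
        level=level,
        model="linear",
    )


def _exposure(schedule: np.ndarray, u: float) -> float:
    """Cumulative site-month exposure of a schedule at trial time u."""
    return float(np.sum(np.maximum(0.0, u - schedule)))


def fit_posterior_sites(
    prior: AccrualPrior,
    interim: InterimState,
    site_schedule: Sequence[float],
) -> PosteriorState:
    """Site-activation-aware conjugate update.

    Exposure is re-expressed in site-months: s(t) = sum over sites of their
    active time up to t, and theta becomes the mean waiting time per
    site-month of exposure. The prior scale uses the planned exposure
    s(T) implied by the same schedule; the posterior is
    InvGamma(P*n + m, P*s(T) + s(t)).
    """
    schedule = np.sort(np.asarray(site_schedule, dtype=float))
    if schedule.size == 0:
        raise ValueError("site schedule is empty")
    s_obs = _exposure(schedule, interim.t)
    if prior.P == 0 and interim.m == 0:
        raise ValueError("posterior improper: non-informative prior with no events")
    if s_obs <= 0 and prior.P == 0:
        raise ValueError("no observed site-month exposure with non-informative prior")
    s_planned = _exposure(schedule, prior.T) if prior.T is not None else 0.0
    shape = prior.P * prior.n + interim.m
    scale = prior.P * s_planned + s_obs
    return PosteriorState(shape=shape, scale=scale, m=interim.m, t=interim.t)


def predict_with_sites(
    prior: AccrualPrior,
    interim: InterimState,
    site_schedule: Sequence[float],
    draws: int = 50_000,
    seed: int | None = None,
    level: float = 0.95,
) -> PredictionResult:
    """Completion-time prediction that integrates the future active-site
    trajectory.

    ``site_schedule`` lists site activation times in months from trial
    start. The residual *exposure* needed to recruit the remaining
    patients is Gamma(remaining, theta) in site-months; it is converted to
    calendar time by inverting the piecewise-linear exposure function of
    the schedule. When every site is active from time 0 this reduces
    exactly to the site-naive model with t replaced by (n_sites * t).
    """
    schedule = np.sort(np.asarray(site_schedule, dtype=float))
    if schedule.size == 0:
        raise ValueError("no future capacity: empty site schedule")
    remaining = interim.remaining
    if remaining == 0:
        return PredictionResult(
            kind="completion_time",
            point=interim.t,
            mean=interim.t,
            interval=(interim.t, interim.t),
            level=level,
            model="bayes_sites",
        )
    post = fit_posterior_sites(prior, interim, schedule)
    rng = np.random.default_rng(seed)
    theta = post.sample_theta(draws, rng)
    needed = rng.standard_gamma(remaining, size=draws) * theta  # site-months

    # invert e(u) = s(u) - s(t): piecewise linear in u with slope = number
    # of active sites; knots at future activations
    t = interim.t
    base = _exposure(schedule, t)
    future_knots = schedule[schedule > t]
    knot_times = np.concatenate(([t], future_knots))
    knot_expo = np.array([_exposure(schedule, u) - base for u in knot_times])
    slope_end = float(schedule.size)  # all sites active past the last knot
    n_active_now = int(np.sum(schedule <= t))
    if n_active_now == 0 and future_knots.size == 0:
        raise ValueError("no future capacity: no site ever activates")

    times = np.interp(needed, knot_expo, knot_times)
    beyond = needed > knot_expo[-1]
    if np.any(beyond):
        times[beyond] = knot_times[-1] + (needed[beyond] - knot_expo[-1]) / slope_end
    # flat initial segment (no active sites yet): np.interp handles ties by
    # returning the first knot; exposure 0 maps to t which is correct
    result = _summarize(times, "completion_time", level, seed, "bayes_sites")
    return result
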