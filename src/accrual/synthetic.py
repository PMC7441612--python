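"""Synthetic multicenter-trial portfolios.

Each trial recruits as a superposition of per-site Poisson processes:
site j has a constant base rate r_j (patients/month) drawn from a gamma
distribution (cross-site heterogeneity), and starts contributing at its
activation time. Optional seasonality thins the process multiplicatively,

    rate_j(t) = r_j * (1 + A * cos(2*pi * (month_of_year(t) - phase) / 12)),

implemented by exact thinning of the dominating homogeneous process with
rate r_j * (1 + A), so waiting times stay exactly exponential when A = 0.
A configurable fraction of trials is cut off early (a fixed multiple of
the rate-implied duration), producing poor-recruitment discontinuations.

All randomness flows from a single portfolio seed; per-trial generators
are seeded with ``SeedSequence((seed, trial_index))`` so any trial can be
re-simulated in isolation and portfolios are reproducible across runs and
platforms.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trial_data import (
    MONTH_DAYS,
    Portfolio,
    RandomizationEvent,
    SiteRecord,
    TrialRecord,
)


@dataclass(frozen=True)
class LogNormalTargets:
    """Recruitment targets: lognormal around ``median``, floored at ``minimum``."""

    median: float = 150.0
    sigma: float = 0.7
    minimum: int = 20

    def draw(self, rng: np.random.Generator) -> int:
        return max(self.minimum, int(round(rng.lognormal(math.log(self.median), self.sigma))))


@dataclass(frozen=True)
class GammaSiteRates:
    """Per-site recruitment rates (patients/site/month): gamma with given
    mean and shape; smaller shape = more cross-site heterogeneity."""

    mean: float = 1.0
    shape: float = 2.0

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.gamma(self.shape, self.mean / self.shape, size=size)


@dataclass(frozen=True)
class SimulationConfig:
    """Portfolio-level generative settings.

    Defaults emulate a mixed portfolio of investigator-initiated trials:
    targets lognormal with median 150 patients, 1-20 sites per trial, one
    patient per site-month on average with gamma heterogeneity, staggered
    activation (mean lag 2 months after the first site), anticipated
    recruitment time equal to the rate-implied duration, and a quarter of
    trials cut off at half their implied duration (the poor-recruitment
    discontinuation arm).
    """

    n_trials: int = 300
    targets: LogNormalTargets = field(default_factory=LogNormalTargets)
    sites_per_trial: tuple[int, int] = (1, 20)  # uniform inclusive range
    site_rate: GammaSiteRates = field(default_factory=GammaSiteRates)
    activation_lag_mean: float = 2.0  # months, exponential; first site at 0
    seasonal_amplitude: float = 0.0
    seasonal_phase: float = 0.0  # calendar month of the rate peak, in [0, 12)
    anticipated_time_multiplier: float = 1.0
    discontinued_fraction: float = 0.25
    discontinuation_cutoff_multiplier: float = 0.5
    target_inflation: float = 1.1  # recruitment target / statistical size
    calendar_start: dt.date = dt.date(2012, 1, 1)
    calendar_span_months: float = 96.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")
        if not 0 <= self.seasonal_amplitude < 1:
            raise ValueError("seasonal amplitude must lie in [0, 1)")
        if self.sites_per_trial[0] < 1 or self.sites_per_trial[1] < self.sites_per_trial[0]:
            raise ValueError("invalid sites_per_trial range")
        if not 0 <= self.discontinued_fraction <= 1:
            raise ValueError("discontinued_fraction must lie in [0, 1]")
        if self.target_inflation < 1:
            raise ValueError("target_inflation must be >= 1")


@dataclass
class TrialTruth:
    """Generative ground truth for one simulated trial."""

    trial_id: str
    site_rates: np.ndarray
    activation_offsets_months: np.ndarray
    origin_date: dt.date
    total_recruitment_months: float  # trial time of the last event
    reached_target: bool
    cutoff_months: float | None


@dataclass
class SyntheticTruth:
    config: SimulationConfig
    trials: dict[str, TrialTruth] = field(default_factory=dict)


def _month_of_year(date: dt.date, months_after: float) -> float:
    """Continuous calendar-month position in [0, 12) of date + offset."""
    base = (date.timetuple().tm_yday - 1) / 365.25 * 12.0
    return (base + months_after) % 12.0


def _simulate_site_events(
    rng: np.random.Generator,
    rate: float,
    start: float,
    horizon: float,
    amplitude: float,
    phase: float,
    origin_month: float,
) -> np.ndarray:
    """Event times (months from trial start) for one site on [start, horizon],
    seasonally thinned. Exact: homogeneous process at rate*(1+A), each point
    kept with probability (1 + A*cos(...)) / (1 + A)."""
    if rate <= 0 or horizon <= start:
        return np.empty(0)
    dominating = rate * (1.0 + amplitude)
    n_exp = dominating * (horizon - start)
    block = max(16, int(n_exp + 4.0 * math.sqrt(n_exp) + 16))
    times = []
    t = start
    while t < horizon:
        waits = rng.exponential(1.0 / dominating, size=block)
        arr = t + np.cumsum(waits)
        inside = arr[arr < horizon]
        times.append(inside)
        if arr[-1] >= horizon:
            break
        t = arr[-1]
    ts = np.concatenate(times) if times else np.empty(0)
    if amplitude > 0 and ts.size:
        cal = (origin_month + ts) % 12.0
        accept = (1.0 + amplitude * np.cos(2.0 * np.pi * (cal - phase) / 12.0)) / (
            1.0 + amplitude
        )
        ts = ts[rng.random(ts.size) < accept]
    return ts


def simulate_trial(
    config: SimulationConfig, trial_seed, trial_id: str = "T1"
) -> tuple[list[RandomizationEvent], list[SiteRecord], TrialRecord, TrialTruth]:
    """Simulate one trial; returns schema-valid events, sites, record, truth."""
    rng = np.random.default_rng(trial_seed)
    origin_offset_days = rng.uniform(0.0, config.calendar_span_months * MONTH_DAYS)
    origin_date = config.calendar_start + dt.timedelta(days=float(origin_offset_days))
    origin_month = _month_of_year(origin_date, 0.0)

    n_sites = int(rng.integers(config.sites_per_trial[0], config.sites_per_trial[1] + 1))
    rates = config.site_rate.draw(rng, n_sites)
    lags = np.zeros(n_sites)
    if n_sites > 1:
        lags[1:] = rng.exponential(config.activation_lag_mean, size=n_sites - 1)

    target = config.targets.draw(rng)
    total_rate = float(np.sum(rates))
    implied_months = target / total_rate
    if implied_months > 1e4:
        raise ValueError(
            f"config implies expected duration {implied_months:.3g} months (> 1e4)"
        )
    cutoff: float | None = None
    if rng.random() < config.discontinued_fraction:
        cutoff = config.discontinuation_cutoff_multiplier * implied_months

    horizon = max(3.0 * implied_months + float(np.max(lags)) + 12.0, 24.0)
    if cutoff is not None:
        horizon = min(horizon, cutoff)
    for _ in range(30):
        per_site = [
            _simulate_site_events(
                rng,
                rates[j],
                lags[j],
                horizon,
                config.seasonal_amplitude,
                config.seasonal_phase,
                origin_month,
            )
            for j in range(n_sites)
        ]
        site_idx = np.concatenate(
            [np.full(ev.size, j, dtype=int) for j, ev in enumerate(per_site)]
        )
        all_times = np.concatenate(per_site)
        order = np.argsort(all_times, kind="stable")
        all_times, site_idx = all_times[order], site_idx[order]
        if all_times.size >= target or cutoff is not None:
            break
        horizon *= 2.0
    reached = all_times.size >= target
    if reached:
        all_times, site_idx = all_times[:target], site_idx[:target]

    events = [
        RandomizationEvent(
            trial_id=trial_id,
            date=origin_date + dt.timedelta(days=float(np.floor(tm * MONTH_DAYS))),
            site_id=f"{trial_id}-S{site_idx[k] + 1}",
        )
        for k, tm in enumerate(all_times)
    ]
    sites = [
        SiteRecord(
            trial_id=trial_id,
            site_id=f"{trial_id}-S{j + 1}",
            activation_date=origin_date + dt.timedelta(days=float(np.floor(lags[j] * MONTH_DAYS))),
            n_randomized=int(np.sum(site_idx == j)),
        )
        for j in range(n_sites)
    ]
    anticipated = config.anticipated_time_multiplier * implied_months
    record = TrialRecord(
        trial_id=trial_id,
        recruitment_target=target,
        statistical_sample_size=max(1, int(round(target / config.target_inflation))),
        anticipated_recruitment_time=anticipated,
        n_sites=n_sites,
        completion_status="completed" if reached else "discontinued",
        discontinuation_reason="none" if reached else "poor_recruitment",
    )
    truth = TrialTruth(
        trial_id=trial_id,
        site_rates=rates,
        activation_offsets_months=lags,
        origin_date=origin_date,
        total_recruitment_months=float(all_times[-1]) if all_times.size else float("nan"),
        reached_target=reached,
        cutoff_months=cutoff,
    )
    return events, sites, record, truth


def simulate_portfolio(config: SimulationConfig) -> tuple[Portfolio, SyntheticTruth]:
    """Simulate ``config.n_trials`` independent trials.

    Trial i uses ``SeedSequence((config.seed, i))`` so the portfolio is
    reproducible and trials are independent.
    """
    events: list[RandomizationEvent] = []
    sites: list[SiteRecord] = []
    trials: dict[str, TrialRecord] = {}
    truth = SyntheticTruth(config=config)
    for i in range(config.n_trials):
        tid = f"T{i + 1:04d}"
        ss = np.random.SeedSequence((config.seed, i))
        ev, st, rec, tr = simulate_trial(config, ss, trial_id=tid)
        events.extend(ev)
        sites.extend(st)
        trials[tid] = rec
        truth.trials[tid] = tr
    return Portfolio(trials=trials, events=events, sites=sites), truth


def write_portfolio(portfolio: Portfolio, directory: str | Path) -> dict[str, Path]:
    """Write patients.csv, sites.csv, trials.csv in the ingestion dialects.

    Round-trips: ``read_portfolio`` on the written files reproduces the
    event multiset, site records and trial metadata.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    patients = pd.DataFrame(
        {
            "trial_id": [e.trial_id for e in portfolio.events],
            "site_id": [e.site_id or "" for e in portfolio.events],
            "randomization_date": [e.date.isoformat() for e in portfolio.events],
        }
    )
    sites = pd.DataFrame(
        {
            "trial_id": [s.trial_id for s in portfolio.sites],
            "site_id": [s.site_id for s in portfolio.sites],
            "activation_date": [
                s.activation_date.isoformat() if s.activation_date else ""
                for s in portfolio.sites
            ],
            "closure_date": [
                s.closure_date.isoformat() if s.closure_date else ""
                for s in portfolio.sites
            ],
            "country": [s.country or "" for s in portfolio.sites],
            "n_randomized": [
                "" if s.n_randomized is None else s.n_randomized
                for s in portfolio.sites
            ],
            "pi_institution": [
                "" if s.pi_institution is None else str(s.pi_institution).lower()
                for s in portfolio.sites
            ],
        }
    )
    recs = [portfolio.trials[tid] for tid in portfolio.trial_ids()]
    trials = pd.DataFrame(
        {
            "trial_id": [r.trial_id for r in recs],
            "recruitment_target": [r.recruitment_target for r in recs],
            "statistical_sample_size": [
                "" if r.statistical_sample_size is None else r.statistical_sample_size
                for r in recs
            ],
            "anticipated_recruitment_time_months": [
                "" if r.anticipated_recruitment_time is None
                else f"{r.anticipated_recruitment_time:.6f}"
                for r in recs
            ],
            "n_sites": ["" if r.n_sites is None else r.n_sites for r in recs],
            "completion_status": [r.completion_status for r in recs],
            "discontinuation_reason": [r.discontinuation_reason for r in recs],
            "medical_field": [r.medical_field or "" for r in recs],
            "intervention_type": [r.intervention_type or "" for r in recs],
            "blinding": [r.blinding or "" for r in recs],
            "setting": [r.setting or "" for r in recs],
            "funding": [r.funding or "" for r in recs],
        }
    )
    paths = {
        "patients": directory / "patients.csv",
        "sites": directory / "sites.csv",
        "trials": directory / "trials.csv",
    }
    patients.to_csv(paths["patients"], index=False)
    sites.to_csv(paths["sites"], index=False)
    trials.to_csv(paths["trials"], index=False)
    return paths
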