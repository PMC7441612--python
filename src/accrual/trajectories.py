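"""Descriptive recruitment-pattern analyses across a trial portfolio.

Covers averaged accrual rates, calendar-month seasonal profiles with a
permutation test, the association of early recruitment slope with final
recruitment success, stratification by site readiness, the comparison of
actual with anticipated recruitment time, and a six-item report of
classical recruitment patterns (early speed predicts attainment, the
second-to-first-month acceleration ratio, the <30%-at-10-months failure
rule, and absence of marked late acceleration).

Every resampling procedure (permutation or bootstrap) takes an explicit
seed. Analyses with empty strata or insufficient exposure raise
:class:`~accrual.trial_data.NotEvaluableError` instead of returning a
number; ``pattern_report`` converts those into "not evaluable" entries.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .trial_data import (
    MONTH_DAYS,
    NotEvaluableError,
    Portfolio,
    RecruitmentTrajectory,
    aggregate_monthly,
    classify_completion,
)


def average_rate(traj: RecruitmentTrajectory) -> float:
    """Overall averaged recruitment rate: total patients / recruitment
    time in months. Undefined for a single-event trajectory."""
    if traj.recruitment_time <= 0:
        raise ValueError(
            f"trial {traj.trial_id}: recruitment time is zero, rate undefined"
        )
    return traj.total / traj.recruitment_time


def _calendar_month_exposure(origin: dt.date, duration_months: float) -> np.ndarray:
    """Days of the active window [origin, origin + duration] spent in each
    calendar month (length-12 vector, January = 0)."""
    exposure = np.zeros(12)
    total_days = duration_months * MONTH_DAYS
    day = origin
    remaining = total_days
    while remaining > 0:
        month_end = (day.replace(day=1) + dt.timedelta(days=32)).replace(day=1)
        in_month = min(remaining, (month_end - day).days)
        exposure[day.month - 1] += in_month
        remaining -= (month_end - day).days
        day = month_end
    return exposure


@dataclass
class SeasonalProfile:
    """Exposure-adjusted calendar-month accrual indices (1 = no seasonal
    effect) with a rotation-permutation p-value."""

    indices: np.ndarray  # length 12, January first
    p_value: float
    n_trials: int
    statistic: float  # chi-square-style deviation of observed from expected


def seasonal_profile(
    portfolio: Portfolio,
    n_permutations: int = 1000,
    seed: int | None = 0,
) -> SeasonalProfile:
    """Seasonal accrual profile across the portfolio.

    For each trial, observed accrual per calendar month is compared with
    the expectation under uniform-in-time accrual over that trial's active
    window (its exposure to each calendar month). The index for month c is
    (summed observed) / (summed expected). The permutation null rotates
    each trial's calendar anchor by an independent uniform offset of 0-11
    months, which preserves each trial's internal accrual pattern while
    destroying calendar alignment.
    """
    obs_list, exp_list = [], []
    for tid in portfolio.trial_ids():
        events = portfolio.events_for(tid)
        if not events:
            continue
        traj = portfolio.trajectory(tid)
        obs = np.zeros(12)
        for e in events:
            obs[e.date.month - 1] += 1
        exposure = _calendar_month_exposure(traj.origin_date, max(traj.recruitment_time, 1e-9))
        if exposure.sum() <= 0:
            continue
        exp = traj.total * exposure / exposure.sum()
        obs_list.append(obs)
        exp_list.append(exp)
    if not obs_list:
        raise NotEvaluableError("no trials with events")
    total_months = sum(
        portfolio.trajectory(t).recruitment_time
        for t in portfolio.trial_ids()
        if portfolio.events_for(t)
    )
    if total_months < 12:
        raise NotEvaluableError(
            f"only {total_months:.1f} trial-months of accrual; need >= 12"
        )
    obs_mat = np.array(obs_list)
    exp_mat = np.array(exp_list)

    def chi2(o: np.ndarray, e: np.ndarray) -> float:
        tot_o, tot_e = o.sum(axis=0), e.sum(axis=0)
        ok = tot_e > 0
        return float(np.sum((tot_o[ok] - tot_e[ok]) ** 2 / tot_e[ok]))

    observed_stat = chi2(obs_mat, exp_mat)
    tot_obs, tot_exp = obs_mat.sum(axis=0), exp_mat.sum(axis=0)
    indices = np.divide(
        tot_obs, tot_exp, out=np.full(12, np.nan), where=tot_exp > 0
    )

    rng = np.random.default_rng(seed)
    n_tr = obs_mat.shape[0]
    exceed = 0
    for _ in range(n_permutations):
        shifts = rng.integers(0, 12, size=n_tr)
        o = np.array([np.roll(obs_mat[i], shifts[i]) for i in range(n_tr)])
        e = np.array([np.roll(exp_mat[i], shifts[i]) for i in range(n_tr)])
        if chi2(o, e) >= observed_stat:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return SeasonalProfile(
        indices=indices, p_value=p, n_trials=n_tr, statistic=observed_stat
    )


@dataclass
class EarlySlopeAssociation:
    correlation: float
    ci_low: float
    ci_high: float
    n_trials: int
    tercile_success: list[float]  # share achieving > 90% of target, by tercile


def early_slope_association(
    portfolio: Portfolio,
    window: float = 3.0,
    n_bootstrap: int = 1000,
    seed: int | None = 0,
    success_threshold: float = 0.90,
) -> EarlySlopeAssociation:
    """Spearman correlation between the fraction of target recruited within
    the first ``window`` months and the final fraction achieved, with a
    percentile bootstrap interval and success shares by early-slope
    tercile."""
    early, final = [], []
    for tid in portfolio.trial_ids():
        events = portfolio.events_for(tid)
        if not events:
            continue
        traj = portfolio.trajectory(tid)
        if traj.recruitment_time < window:
            continue  # window not fully observed
        early.append(traj.count_at(window) / traj.target)
        final.append(traj.total / traj.target)
    if len(early) < 10:
        raise NotEvaluableError(
            f"only {len(early)} trials with {window:g} months of follow-up; need >= 10"
        )
    early_a, final_a = np.array(early), np.array(final)
    if np.unique(early_a).size < 2 or np.unique(final_a).size < 2:
        raise NotEvaluableError("early or final accrual constant across trials")
    rho = float(stats.spearmanr(early_a, final_a).statistic)

    rng = np.random.default_rng(seed)
    n = early_a.size
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        if np.unique(early_a[idx]).size < 2 or np.unique(final_a[idx]).size < 2:
            boots[b] = np.nan
            continue
        boots[b] = stats.spearmanr(early_a[idx], final_a[idx]).statistic
    if np.all(np.isnan(boots)):
        lo = hi = float("nan")
    else:
        lo, hi = np.nanquantile(boots, [0.025, 0.975])

    order = np.argsort(early_a, kind="stable")
    terciles = np.array_split(order, 3)
    tercile_success = [
        float(np.mean(final_a[idx] > success_threshold)) if idx.size else float("nan")
        for idx in terciles
    ]
    return EarlySlopeAssociation(
        correlation=rho,
        ci_low=float(lo),
        ci_high=float(hi),
        n_trials=n,
        tercile_success=tercile_success,
    )


@dataclass
class ReadinessSplit:
    grid_months: np.ndarray
    ready_mean: np.ndarray | None  # mean proportion-of-target trajectory
    slow_mean: np.ndarray | None
    n_ready: int
    n_slow: int
    n_excluded: int  # trials lacking site activation data


def _proportion_on_grid(traj: RecruitmentTrajectory, grid: np.ndarray) -> np.ndarray:
    out = np.empty(grid.size)
    for i, g in enumerate(grid):
        out[i] = min(traj.count_at(g), traj.total) / traj.target
    return out


def site_readiness_split(
    portfolio: Portfolio,
    readiness_fraction: float = 0.80,
    window: float = 1.0,
    grid_max_months: float | None = None,
) -> ReadinessSplit:
    """Partition trials by site readiness and average their normalized
    trajectories.

    A trial is "ready" when more than ``readiness_fraction`` of its sites
    activated within ``window`` months of the trial's first randomization.
    Trials whose sites lack activation dates are excluded and counted.
    """
    ready, slow = [], []
    n_excluded = 0
    for tid in portfolio.trial_ids():
        events = portfolio.events_for(tid)
        sites = portfolio.sites_for(tid)
        if not events:
            continue
        if not sites or any(s.activation_date is None for s in sites):
            n_excluded += 1
            continue
        traj = portfolio.trajectory(tid)
        cutoff = traj.origin_date + dt.timedelta(days=window * MONTH_DAYS)
        frac = np.mean([s.activation_date <= cutoff for s in sites])
        (ready if frac > readiness_fraction else slow).append(traj)
    if not ready and not slow:
        raise NotEvaluableError("no trial has complete site activation data")
    if grid_max_months is None:
        grid_max_months = math.ceil(
            max(t.recruitment_time for t in ready + slow)
        )
    grid = np.arange(0.0, grid_max_months + 1.0)
    ready_mean = (
        np.mean([_proportion_on_grid(t, grid) for t in ready], axis=0) if ready else None
    )
    slow_mean = (
        np.mean([_proportion_on_grid(t, grid) for t in slow], axis=0) if slow else None
    )
    return ReadinessSplit(
        grid_months=grid,
        ready_mean=ready_mean,
        slow_mean=slow_mean,
        n_ready=len(ready),
        n_slow=len(slow),
        n_excluded=n_excluded,
    )


@dataclass
class AnticipatedVsActual:
    ratios: dict[str, float]  # trial_id -> actual / anticipated
    median: float
    q1: float
    q3: float
    n_excluded: int  # anticipated time missing


def anticipated_vs_actual(portfolio: Portfolio) -> AnticipatedVsActual:
    """Distribution of actual / anticipated recruitment time."""
    ratios: dict[str, float] = {}
    n_excluded = 0
    for tid in portfolio.trial_ids():
        rec = portfolio.trials[tid]
        events = portfolio.events_for(tid)
        if not events:
            continue
        if rec.anticipated_recruitment_time is None or rec.anticipated_recruitment_time <= 0:
            n_excluded += 1
            continue
        traj = portfolio.trajectory(tid)
        ratios[tid] = traj.recruitment_time / rec.anticipated_recruitment_time
    if not ratios:
        raise NotEvaluableError("no trial records an anticipated recruitment time")
    vals = np.array(list(ratios.values()))
    q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
    return AnticipatedVsActual(
        ratios=ratios, median=float(med), q1=float(q1), q3=float(q3), n_excluded=n_excluded
    )


@dataclass
class PatternCheck:
    check_id: str
    description: str
    value: float | None
    uncertainty: tuple[float, float] | None
    n_trials: int
    status: str = "ok"  # ok | not_evaluable
    note: str = ""


@dataclass
class PatternReport:
    checks: dict[str, PatternCheck] = field(default_factory=dict)

    def __getitem__(self, key: str) -> PatternCheck:
        return self.checks[key]


def _spearman_with_bootstrap(
    x: np.ndarray, y: np.ndarray, rng: np.random.Generator, n_boot: int = 1000
) -> tuple[float, tuple[float, float]]:
    rho = float(stats.spearmanr(x, y).statistic)
    boots = np.empty(n_boot)
    n = x.size
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.unique(x[idx]).size < 2 or np.unique(y[idx]).size < 2:
            boots[b] = np.nan
            continue
        boots[b] = stats.spearmanr(x[idx], y[idx]).statistic
    if np.all(np.isnan(boots)):
        return rho, (float("nan"), float("nan"))
    lo, hi = np.nanquantile(boots, [0.025, 0.975])
    return rho, (float(lo), float(hi))


def _marked_acceleration(monthly: np.ndarray) -> bool:
    """Operational definition of marked late acceleration of accrual.

    The trailing month bin is dropped (it is censored by the end of
    recruitment); on the remaining bins the flag requires the OLS slope of
    monthly counts over month index to be positive and exceed three times
    its standard error, AND the mean monthly rate from month 12 onward to
    exceed 1.5x the mean over months 1-3. The 3-SE slope criterion keeps
    the false-flag rate per constant-rate trial well below 1%.
    """
    y = monthly[:-1].astype(float)  # last bin censored by recruitment end
    if y.size < 14:
        return False
    x = np.arange(y.size, dtype=float)
    res = stats.linregress(x, y)
    if not (res.slope > 0 and res.stderr > 0 and res.slope > 3 * res.stderr):
        return False
    early = float(np.mean(y[:3]))
    late = float(np.mean(y[12:]))
    if early <= 0:
        return late > 0
    return late > 1.5 * early


def pattern_report(
    portfolio: Portfolio,
    seed: int | None = 0,
    attainment_fraction: float = 1.0,
    origin: str = "first_event",
) -> PatternReport:
    """Six classical recruitment-pattern checks.

    (1) early speed (3-month accrual rate) vs target attainment;
    (2) months-1-2 accrual vs subsequent per-month accrual;
    (3) acceleration ratio (month-2 / month-1 counts) vs eventual accrual;
    (4) 2-month count vs final absolute accrual and vs final proportion of
        target;
    (5) among trials below 30% of target at 10 months, the share that
        eventually reached the target;
    (6) number of trials showing marked late acceleration of accrual.

    ``attainment_fraction`` defines "target attained" as final accrual >=
    that fraction of the recruitment target. With the default
    first-randomization time origin the first month always contains at
    least one patient; ``origin="activation"`` measures months from site
    activation instead, where an empty first month is possible and such
    trials are excluded from the acceleration-ratio check and tallied.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for tid in portfolio.trial_ids():
        events = portfolio.events_for(tid)
        if not events:
            continue
        traj = portfolio.trajectory(tid, origin=origin)
        monthly = aggregate_monthly(traj)
        rows.append(
            {
                "traj": traj,
                "monthly": monthly,
                "final": traj.total,
                "target": traj.target,
                "attained": traj.total >= attainment_fraction * traj.target,
                "cum2": traj.count_at(2.0),
                "cum3": traj.count_at(3.0),
                "cum10": traj.count_at(10.0),
                "duration": traj.recruitment_time,
            }
        )
    if len(rows) < 10:
        raise NotEvaluableError(f"only {len(rows)} classified trials; need >= 10")

    report = PatternReport()

    def add(cid, desc, value, unc, n, status="ok", note=""):
        report.checks[cid] = PatternCheck(cid, desc, value, unc, n, status, note)

    # (1) 3-month speed vs attainment
    x = np.array([r["cum3"] / 3.0 for r in rows])
    y = np.array([float(r["attained"]) for r in rows])
    if np.unique(y).size < 2 or np.unique(x).size < 2:
        add("early_speed_vs_attainment", "3-month accrual speed vs target attainment",
            None, None, len(rows), "not_evaluable", "attainment or speed constant")
    else:
        rho, ci = _spearman_with_bootstrap(x, y, rng)
        add("early_speed_vs_attainment", "3-month accrual speed vs target attainment",
            rho, ci, len(rows))

    # (2) months 1-2 accrual vs subsequent per-month accrual
    sub = [r for r in rows if r["duration"] > 2.0]
    if len(sub) >= 10:
        x2 = np.array([r["cum2"] for r in sub], dtype=float)
        y2 = np.array(
            [(r["final"] - r["cum2"]) / (r["duration"] - 2.0) for r in sub]
        )
        if np.unique(x2).size < 2 or np.unique(y2).size < 2:
            add("early_vs_subsequent",
                "months 1-2 accrual vs subsequent monthly accrual",
                None, None, len(sub), "not_evaluable", "constant input")
        else:
            rho, ci = _spearman_with_bootstrap(x2, y2, rng)
            add("early_vs_subsequent",
                "months 1-2 accrual vs subsequent monthly accrual",
                rho, ci, len(sub))
    else:
        add("early_vs_subsequent", "months 1-2 accrual vs subsequent monthly accrual",
            None, None, len(sub), "not_evaluable", "fewer than 10 trials beyond month 2")

    # (3) acceleration ratio month2/month1 vs eventual accrual
    usable, excluded = [], 0
    for r in rows:
        m1 = r["monthly"][0] if r["monthly"].size >= 1 else 0
        m2 = r["monthly"][1] if r["monthly"].size >= 2 else 0
        if m1 == 0:
            excluded += 1
            continue
        usable.append((m2 / m1, r["final"]))
    if len(usable) >= 10:
        x3 = np.array([u[0] for u in usable])
        y3 = np.array([float(u[1]) for u in usable])
        if np.unique(x3).size < 2 or np.unique(y3).size < 2:
            add("acceleration_ratio_vs_accrual",
                "month-2/month-1 accrual ratio vs eventual accrual",
                None, None, len(usable), "not_evaluable",
                f"constant input; {excluded} trials with empty first month excluded")
        else:
            rho, ci = _spearman_with_bootstrap(x3, y3, rng)
            add("acceleration_ratio_vs_accrual",
                "month-2/month-1 accrual ratio vs eventual accrual",
                rho, ci, len(usable),
                note=f"{excluded} trials with empty first month excluded")
    else:
        add("acceleration_ratio_vs_accrual",
            "month-2/month-1 accrual ratio vs eventual accrual",
            None, None, len(usable), "not_evaluable",
            f"{excluded} trials with empty first month excluded")

    # (4) 2-month count vs final absolute accrual and proportion of target
    x4 = np.array([r["cum2"] for r in rows], dtype=float)
    y4a = np.array([float(r["final"]) for r in rows])
    y4b = np.array([r["final"] / r["target"] for r in rows])
    if np.unique(x4).size < 2:
        add("two_month_count_vs_final", "2-month accrual vs final absolute accrual",
            None, None, len(rows), "not_evaluable", "2-month counts constant")
        add("two_month_count_vs_proportion", "2-month accrual vs final proportion of target",
            None, None, len(rows), "not_evaluable", "2-month counts constant")
    else:
        rho_a, ci_a = _spearman_with_bootstrap(x4, y4a, rng)
        add("two_month_count_vs_final", "2-month accrual vs final absolute accrual",
            rho_a, ci_a, len(rows))
        if np.unique(y4b).size < 2:
            add("two_month_count_vs_proportion",
                "2-month accrual vs final proportion of target",
                None, None, len(rows), "not_evaluable", "final proportions constant")
        else:
            rho_b, ci_b = _spearman_with_bootstrap(x4, y4b, rng)
            add("two_month_count_vs_proportion",
                "2-month accrual vs final proportion of target",
                rho_b, ci_b, len(rows))

    # (5) < 30% of target at 10 months: share eventually reaching target
    stratum = [r for r in rows if r["duration"] >= 10.0 and r["cum10"] < 0.3 * r["target"]]
    stratum += [
        r for r in rows
        if r["duration"] < 10.0 and r["final"] < 0.3 * r["target"]
    ]
    if stratum:
        prop = float(np.mean([r["final"] >= r["target"] for r in stratum]))
        k = int(round(prop * len(stratum)))
        lo, hi = stats.beta.ppf([0.025, 0.975], k + 0.5, len(stratum) - k + 0.5)
        add("slow_at_10_months", "share of trials <30% at 10 months that reached target",
            prop, (float(lo), float(hi)), len(stratum))
    else:
        add("slow_at_10_months", "share of trials <30% at 10 months that reached target",
            None, None, 0, "not_evaluable", "no trial below 30% at 10 months")

    # (6) marked acceleration count
    flagged = sum(_marked_acceleration(r["monthly"]) for r in rows)
    add("marked_acceleration", "trials with marked late acceleration of accrual",
        float(flagged), None, len(rows))

    return report
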