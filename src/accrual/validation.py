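"""Landmark validation of accrual predictions.

For every (trial, landmark, model) triple the engine reconstructs the
interim accrual state, predicts the completion time, and scores the
prediction against the realized recruitment time with the percent
relative error

    %Rbias = |Predicted - True| / True * 100,

an interval-coverage indicator, and (when an anticipated recruitment time
is on record) the risk of accrual failure P_late. The primary run uses
trials that completed or were discontinued for poor recruitment (or for
unknown reasons, which the classification rules treat as presumed poor
recruitment); trials stopped for benefit, harm, futility, external
evidence or administrative reasons enter only a flagged sensitivity run.

"True" recruitment time is the time to the last randomized patient, and
predictions for all trials target the achieved final count, so that
discontinued trials are scored on a quantity they actually realized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import models as am
from .trial_data import (
    DEFAULT_PROPORTION_LANDMARKS,
    DEFAULT_TIME_LANDMARKS,
    MONTH_DAYS,
    InterimState,
    Landmark,
    LandmarkNotReachedError,
    NotEvaluableError,
    Portfolio,
    classify_completion,
)

MODEL_NAMES = ("bayes_informative", "bayes_noninformative", "bayes_sites", "linear")

#: Discontinuation reasons admitted to the primary validation run.
PRIMARY_REASONS = frozenset({"none", "poor_recruitment", "unknown"})

DEFAULT_LANDMARKS: tuple[Landmark, ...] = (
    DEFAULT_TIME_LANDMARKS + DEFAULT_PROPORTION_LANDMARKS
)


@dataclass
class ValidationRow:
    trial_id: str
    landmark: Landmark
    model: str
    predicted: float  # months (completion-time point estimate)
    true_value: float  # months
    rbias_pct: float
    covered: bool | None
    interval: tuple[float, float] | None
    p_late: float | None
    t_pred_point: float
    anticipated_T: float | None
    m: int
    t: float
    sensitivity: bool = False


def percent_rbias(predicted: float, true_value: float) -> float:
    """Absolute relative prediction error in percent."""
    if true_value <= 0:
        raise ValueError("true_value must be positive")
    return abs(predicted - true_value) / true_value * 100.0


@dataclass
class SkipLog:
    """Tally of (trial, landmark, model) combinations that produced no row."""

    entries: list[tuple[str, str, str, str]] = field(default_factory=list)

    def add(self, trial_id: str, landmark: str, model: str, reason: str) -> None:
        self.entries.append((trial_id, landmark, model, reason))


def _model_seed(base_seed: int, i_trial: int, i_lm: int, i_model: int) -> int:
    ss = np.random.SeedSequence((base_seed, i_trial, i_lm, i_model))
    return int(ss.generate_state(1)[0] % (2**31))


def landmark_validate(
    portfolio: Portfolio,
    models: Sequence[str] = ("bayes_informative", "bayes_noninformative", "linear"),
    landmarks: Sequence[Landmark] = DEFAULT_LANDMARKS,
    draws: int = 50_000,
    seed: int = 0,
    prior_weight: float = 0.5,
    include_sensitivity: bool = False,
    skip_log: SkipLog | None = None,
) -> list[ValidationRow]:
    """Run every requested model at every landmark of every eligible trial.

    ``prior_weight`` is the confidence weight P given to the planning
    assumptions (target n, anticipated T) by the informative prior.
    Landmarks a trial has already passed (recruitment finished) and
    proportion landmarks never attained are skipped and tallied in
    ``skip_log``. Returns primary-run rows, plus sensitivity rows (flagged)
    when ``include_sensitivity`` is set.
    """
    unknown = set(models) - set(MODEL_NAMES)
    if unknown:
        raise ValueError(f"unknown model(s) {sorted(unknown)}")
    if skip_log is None:
        skip_log = SkipLog()

    rows: list[ValidationRow] = []
    for i_trial, tid in enumerate(portfolio.trial_ids()):
        rec = portfolio.trials[tid]
        events = portfolio.events_for(tid)
        if not events:
            skip_log.add(tid, "*", "*", "no events")
            continue
        traj = portfolio.trajectory(tid)
        cls = classify_completion(rec, traj.total)
        is_primary = cls.reason in PRIMARY_REASONS
        if not is_primary and not include_sensitivity:
            skip_log.add(tid, "*", "*", f"sensitivity-only ({cls.reason})")
            continue

        true_time = traj.recruitment_time
        achieved = traj.total
        if true_time <= 0:
            skip_log.add(tid, "*", "*", "single-day trial, true time 0")
            continue
        anticipated = rec.anticipated_recruitment_time
        site_schedule = None
        sites = portfolio.sites_for(tid)
        if sites and all(s.activation_date is not None for s in sites):
            site_schedule = [
                (s.activation_date - traj.origin_date).days / MONTH_DAYS for s in sites
            ]

        for i_lm, lm in enumerate(landmarks):
            try:
                state = landmark_state_for_validation(traj, lm)
            except LandmarkNotReachedError:
                skip_log.add(tid, lm.label(), "*", "landmark not reached")
                continue
            if state is None:
                skip_log.add(tid, lm.label(), "*", "recruitment already complete")
                continue
            m, t = state.m, state.t
            remaining = achieved - m
            if remaining < 1:
                skip_log.add(tid, lm.label(), "*", "recruitment already complete")
                continue
            interim = InterimState(m=m, t=t, n=achieved)

            for i_model, model in enumerate(models):
                mseed = _model_seed(seed, i_trial, i_lm, i_model)
                try:
                    pred, plate = _predict_one(
                        model, rec, interim, remaining, site_schedule,
                        draws, mseed, prior_weight, anticipated,
                    )
                except (ValueError, NotEvaluableError) as exc:
                    skip_log.add(tid, lm.label(), model, str(exc))
                    continue
                lo, hi = pred.interval
                rows.append(
                    ValidationRow(
                        trial_id=tid,
                        landmark=lm,
                        model=model,
                        predicted=pred.point,
                        true_value=true_time,
                        rbias_pct=percent_rbias(pred.point, true_time),
                        covered=bool(lo <= true_time <= hi),
                        interval=(lo, hi),
                        p_late=plate,
                        t_pred_point=pred.point,
                        anticipated_T=anticipated,
                        m=m,
                        t=t,
                        sensitivity=not is_primary,
                    )
                )
    if not rows:
        raise NotEvaluableError("empty validation: no evaluable (trial, landmark) pairs")
    return rows


def landmark_state_for_validation(traj, lm: Landmark):
    """Interim state at a landmark, or None when the landmark lies at or
    after the end of recruitment (prediction would be hindsight)."""
    from .trial_data import landmark_state

    if lm.kind == "time_based" and lm.value >= traj.recruitment_time:
        return None
    state = landmark_state(traj, lm)
    if state.t >= traj.recruitment_time:
        return None
    return state


def _predict_one(
    model: str,
    rec,
    interim: InterimState,
    remaining: int,
    site_schedule,
    draws: int,
    seed: int,
    prior_weight: float,
    anticipated: float | None,
):
    if model == "linear":
        pred = am.linear_predict(interim)
        plate = None
    elif model == "bayes_noninformative":
        post = am.fit_posterior(am.AccrualPrior(n=interim.n, P=0.0), interim)
        pred = am.predict_completion_time(post, remaining, draws=draws, seed=seed)
        plate = (
            float(np.mean(pred.draws > anticipated)) if anticipated else None
        )
    elif model == "bayes_informative":
        if anticipated is None or anticipated <= 0:
            raise NotEvaluableError("no anticipated recruitment time for informative prior")
        prior = am.AccrualPrior(n=rec.recruitment_target, T=anticipated, P=prior_weight)
        post = am.fit_posterior(prior, interim)
        pred = am.predict_completion_time(post, remaining, draws=draws, seed=seed)
        plate = float(np.mean(pred.draws > anticipated))
    elif model == "bayes_sites":
        if site_schedule is None:
            raise NotEvaluableError("no complete site activation schedule")
        if anticipated is None or anticipated <= 0:
            raise NotEvaluableError("no anticipated recruitment time for informative prior")
        prior = am.AccrualPrior(n=rec.recruitment_target, T=anticipated, P=prior_weight)
        pred = am.predict_with_sites(
            prior, interim, site_schedule, draws=draws, seed=seed
        )
        plate = float(np.mean(pred.draws > anticipated))
    else:  # pragma: no cover - guarded upstream
        raise ValueError(f"unknown model {model!r}")
    return pred, plate


def rows_to_frame(rows: Sequence[ValidationRow]) -> pd.DataFrame:
    """Flatten validation rows into the CSV dialect."""
    return pd.DataFrame(
        {
            "trial_id": [r.trial_id for r in rows],
            "landmark_kind": [r.landmark.kind for r in rows],
            "landmark_value": [r.landmark.value for r in rows],
            "model": [r.model for r in rows],
            "predicted": [r.predicted for r in rows],
            "true_value": [r.true_value for r in rows],
            "rbias_pct": [r.rbias_pct for r in rows],
            "covered": [r.covered for r in rows],
            "p_late": [r.p_late for r in rows],
            "interval_low": [r.interval[0] if r.interval else None for r in rows],
            "interval_high": [r.interval[1] if r.interval else None for r in rows],
            "m": [r.m for r in rows],
            "t": [r.t for r in rows],
            "anticipated_T": [r.anticipated_T for r in rows],
            "sensitivity": [r.sensitivity for r in rows],
        }
    )


@dataclass
class LandmarkComparison:
    landmark: Landmark
    n_pairs: int
    median_rbias: dict[str, float]
    iqr_rbias: dict[str, tuple[float, float]]
    median_paired_diff: float  # model_a - model_b
    fraction_a_better: float


def compare_models(
    rows: Sequence[ValidationRow],
    model_a: str = "bayes_informative",
    model_b: str = "linear",
) -> list[LandmarkComparison]:
    """Paired per-landmark comparison of two models' %Rbias on common
    (trial, landmark) pairs."""
    primary = [r for r in rows if not r.sensitivity]
    by_key: dict[tuple, dict[str, ValidationRow]] = {}
    for r in primary:
        by_key.setdefault((r.trial_id, r.landmark), {})[r.model] = r
    by_landmark: dict[Landmark, list[tuple[float, float]]] = {}
    for (tid, lm), d in by_key.items():
        if model_a in d and model_b in d:
            by_landmark.setdefault(lm, []).append(
                (d[model_a].rbias_pct, d[model_b].rbias_pct)
            )
    if not by_landmark:
        raise NotEvaluableError(
            f"no common (trial, landmark) pairs for {model_a} vs {model_b}"
        )
    out = []
    for lm in sorted(by_landmark, key=lambda x: (x.kind, x.value)):
        pairs = np.array(by_landmark[lm])
        a, b = pairs[:, 0], pairs[:, 1]
        out.append(
            LandmarkComparison(
                landmark=lm,
                n_pairs=pairs.shape[0],
                median_rbias={
                    model_a: float(np.median(a)),
                    model_b: float(np.median(b)),
                },
                iqr_rbias={
                    model_a: tuple(np.quantile(a, [0.25, 0.75]).tolist()),
                    model_b: tuple(np.quantile(b, [0.25, 0.75]).tolist()),
                },
                median_paired_diff=float(np.median(a - b)),
                fraction_a_better=float(np.mean(a < b)),
            )
        )
    return out


@dataclass
class CoverageCell:
    model: str
    landmark: Landmark
    n: int
    n_covered: int
    coverage: float
    ci_low: float
    ci_high: float


def coverage_summary(
    rows: Sequence[ValidationRow], level: float = 0.95
) -> list[CoverageCell]:
    """Empirical interval coverage per model and landmark, with a
    Jeffreys binomial confidence interval."""
    alpha = 1.0 - level
    cells: dict[tuple, list[bool]] = {}
    for r in rows:
        if r.covered is None or r.sensitivity:
            continue
        cells.setdefault((r.model, r.landmark), []).append(r.covered)
    out = []
    for (model, lm), flags in sorted(
        cells.items(), key=lambda kv: (kv[0][0], kv[0][1].kind, kv[0][1].value)
    ):
        n = len(flags)
        k = int(np.sum(flags))
        lo = stats.beta.ppf(alpha / 2, k + 0.5, n - k + 0.5) if k > 0 else 0.0
        hi = stats.beta.ppf(1 - alpha / 2, k + 0.5, n - k + 0.5) if k < n else 1.0
        out.append(
            CoverageCell(
                model=model,
                landmark=lm,
                n=n,
                n_covered=k,
                coverage=k / n,
                ci_low=float(lo),
                ci_high=float(hi),
            )
        )
    return out


@dataclass
class CalibrationBin:
    low: float
    high: float
    n: int
    mean_p_late: float
    fraction_late: float
    unstable: bool  # fewer than 10 rows


@dataclass
class CalibrationTable:
    bins: list[CalibrationBin]
    monotone: bool  # empirical lateness non-decreasing across stable bins


def p_late_calibration(
    rows: Sequence[ValidationRow], n_bins: int = 10
) -> CalibrationTable:
    """Bin rows by predicted P_late and compare the bin-mean prediction
    with the empirical fraction of trials that finished after their
    anticipated time."""
    usable = [
        r
        for r in rows
        if r.p_late is not None and r.anticipated_T is not None and not r.sensitivity
    ]
    if not usable:
        raise NotEvaluableError("no rows with P_late and an anticipated time")
    p = np.array([r.p_late for r in usable])
    late = np.array([r.true_value > r.anticipated_T for r in usable])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bins = []
    for i in range(n_bins):
        lo, hi = edges[i], edges[i + 1]
        sel = (p >= lo) & (p < hi) if i < n_bins - 1 else (p >= lo) & (p <= hi)
        n = int(np.sum(sel))
        if n == 0:
            continue
        bins.append(
            CalibrationBin(
                low=float(lo),
                high=float(hi),
                n=n,
                mean_p_late=float(np.mean(p[sel])),
                fraction_late=float(np.mean(late[sel])),
                unstable=n < 10,
            )
        )
    stable = [b.fraction_late for b in bins if not b.unstable]
    monotone = all(b2 >= b1 - 1e-12 for b1, b2 in zip(stable, stable[1:]))
    return CalibrationTable(bins=bins, monotone=monotone)
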