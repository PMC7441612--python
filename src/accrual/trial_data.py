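"""Trial-level data model: ingestion, validation, classification, trajectories.

The unit conventions used throughout the package are fixed here:

* dates are ISO-8601 calendar dates (``YYYY-MM-DD``), parsed strictly;
* a month is ``365.25 / 12 = 30.4375`` days, and every day<->month
  conversion goes through :data:`MONTH_DAYS`;
* trial time is measured as day offsets from the date of the first
  randomized patient (optionally from trial activation, see
  :func:`build_trajectory`).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

#: Days per month used for every conversion (365.25 / 12).
MONTH_DAYS: float = 365.25 / 12.0

COMPLETION_STATUSES = ("completed", "discontinued")
DISCONTINUATION_REASONS = (
    "poor_recruitment",
    "benefit",
    "futility",
    "external_evidence",
    "harm",
    "administrative",
    "unknown",
    "none",
)


class SchemaError(ValueError):
    """A table is missing a mandatory column or is otherwise unreadable."""


class RowError(ValueError):
    """One or more rows failed validation; message lists row numbers."""


class ClassificationError(ValueError):
    """A trial cannot be classified (no usable reference sample size)."""


class LandmarkNotReachedError(ValueError):
    """A proportion-based landmark was never attained by the trajectory."""


class NotEvaluableError(ValueError):
    """An analysis has an empty stratum or insufficient data; the result is
    'not evaluable' rather than a number."""


@dataclass(frozen=True)
class RandomizationEvent:
    """One patient's randomization, identified by trial, optional site, date."""

    trial_id: str
    date: dt.date
    site_id: str | None = None

    def __post_init__(self) -> None:
        if not self.trial_id:
            raise ValueError("trial_id must be non-empty")
        if not isinstance(self.date, dt.date):
            raise TypeError("date must be a datetime.date")


@dataclass(frozen=True)
class SiteRecord:
    trial_id: str
    site_id: str
    activation_date: dt.date | None = None
    closure_date: dt.date | None = None
    country: str | None = None
    n_randomized: int | None = None
    pi_institution: bool | None = None

    def __post_init__(self) -> None:
        if (
            self.activation_date is not None
            and self.closure_date is not None
            and self.closure_date < self.activation_date
        ):
            raise ValueError(
                f"site {self.site_id}: closure_date precedes activation_date"
            )


@dataclass
class TrialRecord:
    """Trial-level metadata.

    ``recruitment_target`` is the planned number of patients to randomize;
    ``statistical_sample_size`` is the (typically smaller) statistically
    required size. Inflated targets are common, so a target below the
    statistical size is flagged in ``flags`` rather than rejected.
    """

    trial_id: str
    recruitment_target: int
    statistical_sample_size: int | None = None
    anticipated_recruitment_time: float | None = None  # months
    n_sites: int | None = None
    completion_status: str = "completed"
    discontinuation_reason: str = "none"
    medical_field: str | None = None
    intervention_type: str | None = None
    blinding: str | None = None
    setting: str | None = None
    funding: str | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.trial_id:
            raise ValueError("trial_id must be non-empty")
        if self.recruitment_target < 1:
            raise ValueError("recruitment_target must be a positive integer")
        if self.completion_status not in COMPLETION_STATUSES:
            raise ValueError(f"unknown completion_status {self.completion_status!r}")
        if self.discontinuation_reason not in DISCONTINUATION_REASONS:
            raise ValueError(
                f"unknown discontinuation_reason {self.discontinuation_reason!r}"
            )
        if (
            self.statistical_sample_size is not None
            and self.statistical_sample_size > self.recruitment_target
        ):
            self.flags.append("statistical_sample_size exceeds recruitment_target")

    @property
    def reference_size(self) -> int | None:
        """Denominator for the poor-recruitment rule: the statistical sample
        size when recorded, else the recruitment target."""
        if self.statistical_sample_size is not None:
            return self.statistical_sample_size
        return self.recruitment_target


@dataclass(frozen=True)
class Landmark:
    """An interim monitoring point.

    ``time_based`` landmarks are elapsed months since trial start (the
    conventional grid is months 1, 3, 6, 9 and 12); ``proportion_based``
    landmarks are fractions of the recruitment target (conventionally 10%
    steps).
    """

    kind: Literal["time_based", "proportion_based"]
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("time_based", "proportion_based"):
            raise ValueError(f"unknown landmark kind {self.kind!r}")
        if self.kind == "time_based" and self.value <= 0:
            raise ValueError("time landmark must be positive")
        if self.kind == "proportion_based" and not (0 < self.value <= 1):
            raise ValueError("proportion landmark must lie in (0, 1]")

    def label(self) -> str:
        if self.kind == "time_based":
            return f"month_{self.value:g}"
        return f"prop_{self.value:g}"


DEFAULT_TIME_LANDMARKS = tuple(Landmark("time_based", v) for v in (1, 3, 6, 9, 12))
DEFAULT_PROPORTION_LANDMARKS = tuple(
    Landmark("proportion_based", round(0.1 * k, 1)) for k in range(1, 10)
)


@dataclass(frozen=True)
class InterimState:
    """Accrual state at a monitoring point: ``m`` patients recruited after
    ``t`` elapsed months, against a target of ``n``."""

    m: int
    t: float
    n: int

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("m must be non-negative")
        if self.t < 0:
            raise ValueError("t must be non-negative")
        if self.n < self.m:
            raise ValueError("m must not exceed the target n")

    @property
    def remaining(self) -> int:
        return self.n - self.m


@dataclass
class RecruitmentTrajectory:
    """Cumulative accrual of one trial as a step function of trial time.

    ``offsets`` are day offsets from ``origin_date`` (the first
    randomization, or trial activation when that origin was requested);
    same-day randomizations collapse into one step whose height is the
    number of patients that day.
    """

    trial_id: str
    origin_date: dt.date
    offsets: np.ndarray  # int days, strictly increasing
    cumulative_counts: np.ndarray  # strictly increasing positive ints
    target: int

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.cumulative_counts = np.asarray(self.cumulative_counts, dtype=int)
        if self.offsets.size == 0:
            raise ValueError("trajectory needs at least one event")
        if self.offsets.size != self.cumulative_counts.size:
            raise ValueError("offsets and cumulative_counts differ in length")
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if np.any(np.diff(self.cumulative_counts) < 1) or self.cumulative_counts[0] < 1:
            raise ValueError("cumulative counts must increase by >= 1 per step")

    @property
    def total(self) -> int:
        return int(self.cumulative_counts[-1])

    @property
    def recruitment_time(self) -> float:
        """Months from origin to the last randomization."""
        return float(self.offsets[-1]) / MONTH_DAYS

    def count_at(self, months: float) -> int:
        """Patients randomized strictly before ``months`` (half-open [0, t))."""
        cutoff_days = months * MONTH_DAYS
        # half-open [0, t): an offset exactly at the cutoff is excluded
        idx = int(np.sum(self.offsets < cutoff_days))
        return 0 if idx == 0 else int(self.cumulative_counts[idx - 1])


@dataclass
class Portfolio:
    """A validated collection of trials with their events and sites."""

    trials: dict[str, TrialRecord]
    events: list[RandomizationEvent]
    sites: list[SiteRecord]
    issues: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def events_for(self, trial_id: str) -> list[RandomizationEvent]:
        return [e for e in self.events if e.trial_id == trial_id]

    def sites_for(self, trial_id: str) -> list[SiteRecord]:
        return [s for s in self.sites if s.trial_id == trial_id]

    def trajectory(self, trial_id: str, origin: str = "first_event") -> RecruitmentTrajectory:
        """Accrual trajectory for one trial.

        ``origin="activation"`` measures time from the earliest site
        activation on record instead of the first randomization; trials
        without a usable activation date fall back to the first event.
        """
        activation = None
        if origin == "activation":
            acts = [
                s.activation_date
                for s in self.sites_for(trial_id)
                if s.activation_date is not None
            ]
            events = self.events_for(trial_id)
            if acts and events and min(acts) <= min(e.date for e in events):
                activation = min(acts)
            else:
                origin = "first_event"
        return build_trajectory(
            self.events_for(trial_id),
            self.trials[trial_id],
            origin=origin,
            activation_date=activation,
        )

    def trial_ids(self) -> list[str]:
        return sorted(self.trials)


def _parse_date(value: str) -> dt.date:
    return dt.date.fromisoformat(value)


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def _opt_int(value) -> int | None:
    s = _opt(value)
    return None if s is None else int(float(s))


def _opt_float(value) -> float | None:
    s = _opt(value)
    return None if s is None else float(s)


def _opt_bool(value) -> bool | None:
    s = _opt(value)
    if s is None:
        return None
    low = s.lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot interpret {s!r} as boolean")


def _require_columns(df: pd.DataFrame, required: Sequence[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing mandatory column(s) {missing}")


def read_portfolio(
    patient_table: str | Path,
    site_table: str | Path | None = None,
    trial_table: str | Path | None = None,
) -> Portfolio:
    """Read a portfolio from delimited text tables.

    ``patients.csv`` must carry ``trial_id, site_id, randomization_date``;
    ``sites.csv`` and ``trials.csv`` are optional. Rows that fail
    validation are reported with their 1-based data row numbers in a
    :class:`RowError`; a missing mandatory column raises :class:`SchemaError`.
    Trials present in the patient table but absent from the trial table get
    a minimal record with the achieved count as its target, flagged.
    """
    patients = pd.read_csv(patient_table, dtype=str, keep_default_na=False)
    _require_columns(patients, ["trial_id", "randomization_date"], "patients")

    errors: list[str] = []
    events: list[RandomizationEvent] = []
    for i, row in enumerate(patients.itertuples(index=False), start=1):
        try:
            date = _parse_date(str(row.randomization_date))
            site = _opt(getattr(row, "site_id", None))
            events.append(RandomizationEvent(str(row.trial_id), date, site))
        except (ValueError, TypeError) as exc:
            errors.append(
                f"patients row {i}: bad value "
                f"{row.randomization_date!r} ({exc})"
            )

    sites: list[SiteRecord] = []
    if site_table is not None and Path(site_table).exists():
        site_df = pd.read_csv(site_table, dtype=str, keep_default_na=False)
        _require_columns(site_df, ["trial_id", "site_id"], "sites")
        for i, row in enumerate(site_df.itertuples(index=False), start=1):
            try:
                act = _opt(getattr(row, "activation_date", None))
                clo = _opt(getattr(row, "closure_date", None))
                sites.append(
                    SiteRecord(
                        trial_id=str(row.trial_id),
                        site_id=str(row.site_id),
                        activation_date=_parse_date(act) if act else None,
                        closure_date=_parse_date(clo) if clo else None,
                        country=_opt(getattr(row, "country", None)),
                        n_randomized=_opt_int(getattr(row, "n_randomized", None)),
                        pi_institution=_opt_bool(getattr(row, "pi_institution", None)),
                    )
                )
            except ValueError as exc:
                errors.append(f"sites row {i}: {exc}")

    trials: dict[str, TrialRecord] = {}
    issues: list[str] = []
    if trial_table is not None and Path(trial_table).exists():
        trial_df = pd.read_csv(trial_table, dtype=str, keep_default_na=False)
        _require_columns(trial_df, ["trial_id", "recruitment_target"], "trials")
        for i, row in enumerate(trial_df.itertuples(index=False), start=1):
            try:
                rec = TrialRecord(
                    trial_id=str(row.trial_id),
                    recruitment_target=int(float(row.recruitment_target)),
                    statistical_sample_size=_opt_int(
                        getattr(row, "statistical_sample_size", None)
                    ),
                    anticipated_recruitment_time=_opt_float(
                        getattr(row, "anticipated_recruitment_time_months", None)
                    ),
                    n_sites=_opt_int(getattr(row, "n_sites", None)),
                    completion_status=_opt(getattr(row, "completion_status", None))
                    or "completed",
                    discontinuation_reason=_opt(
                        getattr(row, "discontinuation_reason", None)
                    )
                    or "none",
                    medical_field=_opt(getattr(row, "medical_field", None)),
                    intervention_type=_opt(getattr(row, "intervention_type", None)),
                    blinding=_opt(getattr(row, "blinding", None)),
                    setting=_opt(getattr(row, "setting", None)),
                    funding=_opt(getattr(row, "funding", None)),
                )
                trials[rec.trial_id] = rec
            except ValueError as exc:
                errors.append(f"trials row {i}: {exc}")

    if errors:
        raise RowError("; ".join(errors))

    for tid in sorted({e.trial_id for e in events}):
        if tid not in trials:
            n = sum(1 for e in events if e.trial_id == tid)
            trials[tid] = TrialRecord(
                trial_id=tid, recruitment_target=n, flags=["no trial-level record"]
            )
            issues.append(f"trial {tid}: no trial-level record; target set to {n}")

    return Portfolio(trials=trials, events=events, sites=sites, issues=issues)


@dataclass(frozen=True)
class Classification:
    status: str  # completed | discontinued
    reason: str  # 'none' when completed


def classify_completion(
    trial: TrialRecord,
    achieved: int,
    threshold: float = 0.90,
    inclusive: bool = False,
) -> Classification:
    """Classify a trial as completed or discontinued.

    A stated discontinuation reason always wins. Otherwise the trial is
    discontinued "due to unknown reason" when the achieved count falls
    below ``threshold`` times the reference size (the statistical sample
    size when recorded, else the recruitment target). The primary rule is
    strict (< 90%); the 80% sensitivity rule is "80% or less", selected
    with ``inclusive=True``.
    """
    if achieved < 0:
        raise ValueError("achieved must be non-negative")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if trial.completion_status == "discontinued" and trial.discontinuation_reason != "none":
        return Classification("discontinued", trial.discontinuation_reason)
    reference = trial.reference_size
    if reference is None:
        raise ClassificationError(f"trial {trial.trial_id}: unclassifiable, no reference size")
    cut = threshold * reference
    short = achieved <= cut if inclusive else achieved < cut
    if short:
        return Classification("discontinued", "unknown")
    return Classification("completed", "none")


def build_trajectory(
    events: Iterable[RandomizationEvent],
    trial: TrialRecord,
    origin: str = "first_event",
    activation_date: dt.date | None = None,
) -> RecruitmentTrajectory:
    """Build the cumulative accrual step function for one trial.

    ``origin`` is ``"first_event"`` (default, recruitment time runs from the
    first randomized patient) or ``"activation"`` with ``activation_date``
    given, measuring from trial activation instead.
    """
    events = list(events)
    if not events:
        raise ValueError(f"trial {trial.trial_id}: no randomizations")
    dates = sorted(e.date for e in events)
    if origin == "first_event":
        origin_date = dates[0]
    elif origin == "activation":
        if activation_date is None:
            raise ValueError("origin='activation' requires activation_date")
        if activation_date > dates[0]:
            raise ValueError("activation_date after first randomization")
        origin_date = activation_date
    else:
        raise ValueError(f"unknown origin {origin!r}")

    offsets_all = np.array([(d - origin_date).days for d in dates], dtype=int)
    uniq, counts = np.unique(offsets_all, return_counts=True)
    return RecruitmentTrajectory(
        trial_id=trial.trial_id,
        origin_date=origin_date,
        offsets=uniq,
        cumulative_counts=np.cumsum(counts),
        target=trial.recruitment_target,
    )


def landmark_state(traj: RecruitmentTrajectory, lm: Landmark) -> InterimState:
    """Extract the interim accrual state at a landmark.

    Time-based landmarks count events strictly before the landmark
    (half-open [0, t) in days). Proportion-based landmarks locate the first
    offset at which cumulative accrual reaches ``ceil(value * target)``;
    unreached proportions raise :class:`LandmarkNotReachedError`.
    """
    if lm.kind == "time_based":
        m = traj.count_at(lm.value)
        return InterimState(m=m, t=float(lm.value), n=traj.target)
    required = math.ceil(lm.value * traj.target)
    idx = np.searchsorted(traj.cumulative_counts, required, side="left")
    if idx >= traj.cumulative_counts.size:
        raise LandmarkNotReachedError(
            f"trial {traj.trial_id}: landmark not reached "
            f"({lm.value:.0%} of target {traj.target})"
        )
    t = float(traj.offsets[idx]) / MONTH_DAYS
    return InterimState(m=int(traj.cumulative_counts[idx]), t=t, n=traj.target)


def aggregate_monthly(traj: RecruitmentTrajectory) -> np.ndarray:
    """Monthly accrual counts: bin k covers trial months [k, k+1).

    Interior empty months appear as zeros; the bins sum to the total
    accrual.
    """
    month_idx = np.floor(traj.offsets / MONTH_DAYS).astype(int)
    step_heights = np.diff(traj.cumulative_counts, prepend=0)
    n_bins = int(month_idx[-1]) + 1
    out = np.zeros(n_bins, dtype=int)
    np.add.at(out, month_idx, step_heights)
    return out
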