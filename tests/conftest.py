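import datetime as dt

import numpy as np
import pytest

from accrual.synthetic import SimulationConfig, simulate_portfolio
from accrual.trial_data import Portfolio, RandomizationEvent, TrialRecord


@pytest.fixture(scope="session")
def sim_portfolio():
    """A small simulated portfolio shared by read-only tests."""
    cfg = SimulationConfig(n_trials=25, seed=11)
    portfolio, truth = simulate_portfolio(cfg)
    return portfolio, truth, cfg


def make_linear_trial(
    trial_id: str,
    n: int,
    per_day: int = 1,
    start: dt.date = dt.date(2018, 1, 1),
    target: int | None = None,
    anticipated: float | None = None,
) -> tuple[list[RandomizationEvent], TrialRecord]:
    """Deterministic accrual: ``per_day`` patients every day from ``start``."""
    events = [
        RandomizationEvent(trial_id, start + dt.timedelta(days=k // per_day))
        for k in range(n)
    ]
    rec = TrialRecord(
        trial_id=trial_id,
        recruitment_target=target if target is not None else n,
        anticipated_recruitment_time=anticipated,
    )
    return events, rec


@pytest.fixture()
def linear_portfolio():
    """Twelve deterministic 1-per-day trials with staggered sizes."""
    events, trials = [], {}
    for i, n in enumerate([60, 80, 100, 120, 140, 160, 180, 200, 220, 240, 260, 280]):
        ev, rec = make_linear_trial(f"L{i}", n, anticipated=n / 30.4375)
        events.extend(ev)
        trials[rec.trial_id] = rec
    return Portfolio(trials=trials, events=events, sites=[])
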