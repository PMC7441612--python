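"""Static matplotlib figures for recruitment reports."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .trajectories import ReadinessSplit, SeasonalProfile
from .trial_data import Portfolio
from .validation import CoverageCell, LandmarkComparison, ValidationRow


def trajectory_spaghetti(portfolio: Portfolio, path: str | Path) -> Path:
    """Normalized (proportion-of-target) accrual curves, one line per trial."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for tid in portfolio.trial_ids():
        if not portfolio.events_for(tid):
            continue
        traj = portfolio.trajectory(tid)
        months = traj.offsets / (365.25 / 12.0)
        ax.step(
            months,
            traj.cumulative_counts / traj.target,
            where="post",
            alpha=0.35,
            lw=0.8,
        )
    ax.axhline(1.0, color="k", ls=":", lw=0.8)
    ax.set_xlabel("months since first randomization")
    ax.set_ylabel("proportion of recruitment target")
    ax.set_title("Recruitment trajectories")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def seasonal_bar(profile: SeasonalProfile, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(7, 3.5))
    months = ["J", "F", "M", "A", "M", "J", "J", "A", "S", "O", "N", "D"]
    ax.bar(np.arange(12), profile.indices, color="steelblue")
    ax.axhline(1.0, color="k", ls=":", lw=0.8)
    ax.set_xticks(np.arange(12), months)
    ax.set_ylabel("accrual index (1 = uniform)")
    ax.set_title(f"Seasonal accrual profile (permutation p = {profile.p_value:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def readiness_curves(split: ReadinessSplit, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(7, 4))
    if split.ready_mean is not None:
        ax.plot(split.grid_months, split.ready_mean, label=f"ready (n={split.n_ready})")
    if split.slow_mean is not None:
        ax.plot(split.grid_months, split.slow_mean, label=f"slow (n={split.n_slow})")
    ax.set_xlabel("months since first randomization")
    ax.set_ylabel("mean proportion of target")
    ax.set_title("Mean trajectories by site readiness")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def rbias_curves(comparisons: Sequence[LandmarkComparison], path: str | Path) -> Path:
    """Median %Rbias against time-based landmark month, per model."""
    timed = [c for c in comparisons if c.landmark.kind == "time_based"]
    fig, ax = plt.subplots(figsize=(7, 4))
    if timed:
        xs = [c.landmark.value for c in timed]
        for model in timed[0].median_rbias:
            ax.plot(xs, [c.median_rbias[model] for c in timed], marker="o", label=model)
        ax.legend()
    ax.set_xlabel("landmark (months)")
    ax.set_ylabel("median %Rbias")
    ax.set_title("Prediction error over interim landmarks")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def coverage_bars(cells: Sequence[CoverageCell], level: float, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(8, 4))
    labels = [f"{c.model}\n{c.landmark.label()}" for c in cells]
    ax.bar(np.arange(len(cells)), [c.coverage for c in cells], color="slategray")
    ax.axhline(level, color="firebrick", ls="--", lw=1, label=f"nominal {level:.0%}")
    ax.set_xticks(np.arange(len(cells)), labels, rotation=90, fontsize=6)
    ax.set_ylabel("empirical coverage")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def predictive_distribution(draws: np.ndarray, T: float | None, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.hist(draws, bins=80, density=True, color="steelblue", alpha=0.8)
    if T is not None:
        ax.axvline(T, color="firebrick", ls="--", label=f"anticipated T = {T:g}")
        ax.legend()
    ax.set_xlabel("predicted completion time (months)")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
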