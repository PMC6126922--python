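"""Counterbalanced trial-sequence generation for the probabilistic
cued task-switching design.

A session consists of ``n_runs`` runs of ``trials_per_run`` trials. Each
trial shows a probabilistic pre-cue (the probability that the upcoming
trial is a color rather than a motion task) followed by the task itself.
Within every run the design is counterbalanced so that

* each pre-cue level appears exactly ``trials_per_level_per_run`` times,
* the number of color trials at level ``p`` is ``round(trials_per_level *
  p)`` — the cue is therefore exactly valid within the run,
* half of all trials are color tasks, and
* (optionally) switch and repeat transitions are exactly balanced.

Transition balance classifies the first trial of each run against the last
trial of the previous run; run 1 is classified against a discarded burn-in
task drawn from the seed. This yields ``trials_per_run`` classifiable
transitions per run and an exact half/half split, which is impossible for
the ``trials_per_run - 1`` within-run transitions alone.

Sequences are built by seeded rejection sampling over random permutations
of the counterbalanced (level, task) multiset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import as_rng

__all__ = ["DesignConfig", "ConstraintInfeasibleError", "generate_trial_sequence"]

#: Rejection-sampling attempt cap per run.
MAX_ATTEMPTS = 100_000


class ConstraintInfeasibleError(RuntimeError):
    """Raised when no sequence satisfying the design constraints is found."""


@dataclass(frozen=True)
class DesignConfig:
    """Counterbalancing parameters of one session."""

    n_runs: int = 9
    trials_per_run: int = 50
    precue_levels: tuple[float, ...] = (0.2, 0.4, 0.5, 0.6, 0.8)
    trials_per_level_per_run: int = 10
    enforce_equal_switch: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.n_runs < 1 or self.trials_per_run < 1:
            raise ValueError("n_runs and trials_per_run must be positive")
        levels = tuple(float(p) for p in self.precue_levels)
        if any(not 0.0 < p < 1.0 for p in levels):
            raise ValueError("pre-cue levels must lie strictly inside (0, 1)")
        for p in levels:
            if not (math.isclose(p, 0.5) or any(math.isclose(p + q, 1.0) for q in levels)):
                raise ValueError(
                    "pre-cue levels must include 0.5 or come in complementary pairs"
                )
        if self.trials_per_level_per_run * len(levels) != self.trials_per_run:
            raise ValueError(
                "trials_per_level_per_run x number of levels must equal trials_per_run"
            )

    @property
    def color_counts(self) -> dict[float, int]:
        """Color-task count at each pre-cue level within one run."""
        return {
            float(p): int(round(self.trials_per_level_per_run * p))
            for p in self.precue_levels
        }


def _run_pairs(config: DesignConfig) -> tuple[np.ndarray, np.ndarray]:
    """The counterbalanced (precue, task) multiset of a single run."""
    levels, tasks = [], []
    for p, n_color in config.color_counts.items():
        levels.extend([p] * config.trials_per_level_per_run)
        tasks.extend([1] * n_color + [0] * (config.trials_per_level_per_run - n_color))
    return np.asarray(levels, dtype=float), np.asarray(tasks, dtype=int)


def generate_trial_sequence(
    config: DesignConfig,
    seed: int | None = None,
    subject: str = "s01",
) -> pd.DataFrame:
    """Generate one subject's counterbalanced session.

    Returns a trial table with columns ``subject run trial task precue rt
    correct`` (behavior columns NA); rows chronological, ``trial`` 1-based
    across the session. Deterministic given ``(config, seed)``.
    """
    rng = as_rng(config.seed if seed is None else seed)
    levels, tasks = _run_pairs(config)
    n = config.trials_per_run

    n_color_run = int(tasks.sum())
    if config.enforce_equal_switch and (
        n % 2 != 0 or 2 * n_color_run != n
    ):
        raise ConstraintInfeasibleError(
            "equal switch/repeat balance needs an even run length with half "
            "color trials"
        )

    prev_task = int(rng.integers(2))  # discarded burn-in trial before run 1
    rows_run, rows_level, rows_task = [], [], []
    for run in range(1, config.n_runs + 1):
        for attempt in range(MAX_ATTEMPTS):
            order = rng.permutation(n)
            t = tasks[order]
            if not config.enforce_equal_switch:
                break
            chain_prev = np.concatenate(([prev_task], t[:-1]))
            if int(np.sum(t != chain_prev)) == n // 2:
                break
        else:
            raise ConstraintInfeasibleError(
                f"no balanced sequence found for run {run} in {MAX_ATTEMPTS} attempts"
            )
        rows_run.append(np.full(n, run))
        rows_level.append(levels[order])
        rows_task.append(t)
        prev_task = int(t[-1])

    table = pd.DataFrame(
        {
            "subject": subject,
            "run": np.concatenate(rows_run).astype(int),
            "trial": np.arange(1, config.n_runs * n + 1),
            "task": np.concatenate(rows_task).astype(int),
            "precue": np.concatenate(rows_level),
            "rt": np.nan,
            "correct": np.nan,
        }
    )
    return table
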