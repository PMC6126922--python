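"""Adaptive staircase that titrates stimulus noise before the main task.

Color and motion noise levels start at 0.5 and are re-evaluated at every
5th trial of the corresponding feature (a *checkpoint*):

1. if at most one error was made on that feature since its last
   checkpoint, its noise level increases by 0.025 (harder);
2. if a feature's noise level did not change at any of the past 4
   checkpoints, it decreases by 0.1 (easier).

Levels are clamped to [0.1, 0.9]; the two features are tracked
independently. An update suppressed by the clamp counts as "no change"
for rule 2. The simulated participant is an :class:`ObserverModel`
mapping noise to probability correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from ._utils import as_rng

__all__ = [
    "StaircaseConfig",
    "ObserverModel",
    "logistic_observer",
    "simulate_staircase",
]

FEATURES = ("motion", "color")


@dataclass(frozen=True)
class StaircaseConfig:
    start_noise: float = 0.5
    increment: float = 0.025
    decrement: float = 0.1
    checkpoint_every: int = 5
    stagnation_window: int = 4
    bounds: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self):
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError("bounds must be an increasing pair")
        if not lo <= self.start_noise <= hi:
            raise ValueError("start_noise must lie inside bounds")
        if self.increment <= 0 or self.decrement <= 0:
            raise ValueError("increment and decrement must be positive")
        if self.increment >= self.decrement:
            raise ValueError("increment must be smaller than decrement")
        if self.checkpoint_every < 1 or self.stagnation_window < 1:
            raise ValueError("checkpoint_every and stagnation_window must be >= 1")


@dataclass(frozen=True)
class ObserverModel:
    """Simulated participant: accuracy as a function of stimulus noise.

    ``accuracy_fn`` must map noise levels to probability correct in
    [0.5, 1], monotonically non-increasing in noise (validated on a grid
    at construction).
    """

    accuracy_fn: Callable[[float], float]

    def __post_init__(self):
        grid = np.linspace(0.0, 1.0, 41)
        acc = np.array([float(self.accuracy_fn(g)) for g in grid])
        if np.any(acc < 0.5 - 1e-9) or np.any(acc > 1.0 + 1e-9):
            raise ValueError("observer accuracy must lie in [0.5, 1]")
        if np.any(np.diff(acc) > 1e-9):
            raise ValueError("observer accuracy must be non-increasing in noise")


def logistic_observer(threshold: float = 0.5, slope: float = 0.1, lapse: float = 0.02) -> ObserverModel:
    """Convenience psychometric observer: a descending logistic in noise.

    Accuracy is ``0.5 + (0.5 - lapse) / (1 + exp((noise - threshold) /
    slope))`` — near-perfect well below threshold, chance well above.
    """

    def acc(noise: float) -> float:
        return 0.5 + (0.5 - lapse) / (1.0 + np.exp((noise - threshold) / slope))

    return ObserverModel(accuracy_fn=acc)


def simulate_staircase(
    observer: ObserverModel,
    config: StaircaseConfig,
    n_trials: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run the two-feature staircase against a simulated observer.

    Feature labels are assigned 50/50 at random per trial. Returns a
    trajectory with one row per trial: ``trial`` (1-based), ``feature``,
    ``noise`` (level in force on that trial for that feature) and
    ``correct``.
    """
    if n_trials < config.checkpoint_every:
        raise ValueError("n_trials must be at least checkpoint_every")
    rng = as_rng(seed)
    lo, hi = config.bounds
    noise = {f: config.start_noise for f in FEATURES}
    errors = {f: 0 for f in FEATURES}  # errors since last checkpoint
    count = {f: 0 for f in FEATURES}  # feature trials since last checkpoint
    changed_hist: dict[str, list[bool]] = {f: [] for f in FEATURES}

    rows = []
    for trial in range(1, n_trials + 1):
        feat = FEATURES[int(rng.integers(2))]
        level = noise[feat]
        correct = bool(rng.random() < float(observer.accuracy_fn(level)))
        rows.append((trial, feat, level, correct))
        count[feat] += 1
        errors[feat] += not correct
        if count[feat] == config.checkpoint_every:
            old = noise[feat]
            if errors[feat] <= 1:  # rule 1: performing well -> harder
                noise[feat] = min(hi, old + config.increment)
            hist = changed_hist[feat]
            hist.append(noise[feat] != old)
            w = config.stagnation_window
            if not hist[-1] and len(hist) >= w and not any(hist[-w:]):
                noise[feat] = max(lo, noise[feat] - config.decrement)  # rule 2
                hist[-1] = noise[feat] != old
            count[feat] = 0
            errors[feat] = 0

    return pd.DataFrame(rows, columns=["trial", "feature", "noise", "correct"])
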