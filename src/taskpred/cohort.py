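"""Generative behavioral model: subject parameters, cohort sampling and
RT/accuracy simulation.

A subject is characterised by a learning rate ``alpha`` (delta-rule
internal prediction), a cue reliance ``beta`` (weight of the pre-cue in
the joint prediction) and the RT model

    rt = c0_task + c_cue * PE_cue + c_int * PE_int + eps,
    eps ~ Normal(0, sigma^2),

truncated to a plausible response window. ``beta = c_cue / (c_cue +
c_int)``, so the regression weights and the cue reliance are two views of
the same quantity. Accuracy is Bernoulli with p = clip(acc_base -
acc_slope * PE_joint, 0.5, 1): the less the joint prediction matched the
actual task, the more errors.

Population defaults follow the behavioral ranges the framework was
developed on: alpha uniform on [0.02, 0.93], beta Beta-distributed with
mean 0.26, task intercepts 0.84 s (motion) and 0.97 s (color).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import as_rng
from .variables import compute_model_variables

__all__ = ["SubjectParams", "PopulationSpec", "sample_cohort", "simulate_behavior"]

#: Simulated RTs are truncated to this window (seconds).
RT_BOUNDS = (0.2, 3.0)


@dataclass(frozen=True)
class SubjectParams:
    """Generative (or fitted) parameters of one subject."""

    alpha: float
    beta: float
    c_cue: float
    c_int: float
    c0_motion: float = 0.84
    c0_color: float = 0.97
    sigma: float = 0.1
    acc_base: float = 0.97
    acc_slope: float = 0.2

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if self.c_cue < 0 or self.c_int < 0 or self.sigma < 0:
            raise ValueError("c_cue, c_int and sigma must be non-negative")
        total = self.c_cue + self.c_int
        if total > 0 and abs(self.beta - self.c_cue / total) > 1e-9:
            raise ValueError("beta must equal c_cue / (c_cue + c_int)")

    @staticmethod
    def from_weights(alpha: float, c_cue: float, c_int: float, **kwargs) -> "SubjectParams":
        total = c_cue + c_int
        beta = c_cue / total if total > 0 else 0.0
        return SubjectParams(alpha=alpha, beta=beta, c_cue=c_cue, c_int=c_int, **kwargs)

    @staticmethod
    def from_beta(alpha: float, beta: float, c_int: float = 0.15, **kwargs) -> "SubjectParams":
        """Build from (alpha, beta) with c_cue = beta * c_int / (1 - beta)."""
        if beta >= 1.0:
            raise ValueError("beta must be < 1 to derive c_cue from c_int")
        return SubjectParams(
            alpha=alpha, beta=beta, c_cue=beta * c_int / (1.0 - beta), c_int=c_int, **kwargs
        )


@dataclass(frozen=True)
class PopulationSpec:
    """Distributional description of a cohort.

    ``alpha_dist`` / ``beta_dist`` name the sampling law: ``uniform``
    (low/high), ``beta`` (mean, concentration a) or ``constant`` (value).
    ``c_int`` is fixed per cohort; ``c_cue`` is derived from beta.
    """

    alpha_dist: str = "uniform"
    alpha_low: float = 0.02
    alpha_high: float = 0.93
    alpha_value: float = 0.5
    beta_dist: str = "beta"
    beta_mean: float = 0.26
    beta_a: float = 2.0
    beta_value: float = 0.26
    c_int: float = 0.15
    c0_motion: float = 0.84
    c0_color: float = 0.97
    sigma: float = 0.1
    acc_base: float = 0.97
    acc_slope: float = 0.2

    def __post_init__(self):
        for name in (self.alpha_dist, self.beta_dist):
            if name not in ("uniform", "beta", "constant"):
                raise ValueError(f"unsupported distribution {name!r}")
        if not 0.0 < self.beta_mean < 1.0:
            raise ValueError("beta_mean must be in (0, 1)")


def _draw(dist: str, rng: np.random.Generator, n: int, spec: PopulationSpec, which: str) -> np.ndarray:
    if dist == "uniform":
        lo, hi = (spec.alpha_low, spec.alpha_high)
        return rng.uniform(lo, hi, n)
    if dist == "beta":
        a = spec.beta_a
        b = a * (1.0 - spec.beta_mean) / spec.beta_mean
        return rng.beta(a, b, n)
    # constant
    return np.full(n, spec.alpha_value if which == "alpha" else spec.beta_value)


def sample_cohort(
    n: int,
    population: PopulationSpec | None = None,
    seed: int | None = None,
) -> list[SubjectParams]:
    """Draw ``n`` subjects' generative parameters from a population spec."""
    spec = population or PopulationSpec()
    rng = as_rng(seed)
    alphas = _draw(spec.alpha_dist, rng, n, spec, "alpha")
    betas = _draw(spec.beta_dist, rng, n, spec, "beta")
    return [
        SubjectParams.from_beta(
            alpha=float(a),
            beta=float(b),
            c_int=spec.c_int,
            c0_motion=spec.c0_motion,
            c0_color=spec.c0_color,
            sigma=spec.sigma,
            acc_base=spec.acc_base,
            acc_slope=spec.acc_slope,
        )
        for a, b in zip(alphas, betas)
    ]


def simulate_behavior(
    trials: pd.DataFrame,
    params: SubjectParams,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fill ``rt`` and ``correct`` of a designed trial table.

    RTs follow the linear PE model above, truncated to [0.2, 3] s;
    accuracy is Bernoulli in PE_joint. Deterministic given the seed.
    """
    rng = as_rng(seed)
    vars_df = compute_model_variables(trials, params.alpha, params.beta)
    n = len(vars_df)
    c0 = np.where(vars_df["task"].to_numpy() == 1, params.c0_color, params.c0_motion)
    rt = (
        c0
        + params.c_cue * vars_df["PE_cue"].to_numpy()
        + params.c_int * vars_df["PE_int"].to_numpy()
        + rng.normal(0.0, params.sigma, n)
    )
    rt = np.clip(rt, *RT_BOUNDS)
    p_correct = np.clip(
        params.acc_base - params.acc_slope * vars_df["PE_joint"].to_numpy(), 0.5, 1.0
    )
    correct = (rng.random(n) < p_correct).astype(float)
    out = trials.reset_index(drop=True).copy()
    out["rt"] = rt
    out["correct"] = correct
    return out
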