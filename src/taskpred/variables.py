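"""Model variables of the joint-guidance framework.

On every trial the subject holds three graded predictions of the upcoming
task (coded 0 = motion, 1 = color):

* ``P_cue`` — the probability announced by the probabilistic pre-cue;
* ``P_int`` — an internally generated, trial-history based prediction
  updated by a delta rule with learning rate ``alpha``:
  ``P_int(i) = (1 - alpha) * P_int(i-1) + alpha * T_prev``, initialised at
  0.5 (unbiased belief) at the start of the session;
* ``P_joint`` — their convex combination ``(1 - beta) * P_int + beta *
  P_cue`` where ``beta`` is the subject's scaled reliance on the cue.

Unsigned prediction errors ``PE_x = |T_cur - P_x|`` index the amount of
reactive task-set updating each prediction leaves to be done, and three
derived quantities describe proactive demand: ``|T_prev - P_joint|``
(proactive switch demand), ``|P_joint - 0.5|`` (prediction confidence) and
``|P_int - P_cue|`` (proactive interference between the two sources).

The first trial of a session has no predecessor: ``T_prev``, ``PE_prev``
and proactive switch demand are NaN there and the trial is excluded from
model fits downstream. ``P_int`` carries across run boundaries within a
session (single continuous recursion); restarting it is the caller's
choice (e.g. for split-half fits).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "internal_prediction_series",
    "joint_prediction",
    "compute_model_variables",
    "prediction_errors",
    "demand_variables",
    "VARIABLE_COLUMNS",
]

#: Columns appended to a trial table by :func:`compute_model_variables`.
VARIABLE_COLUMNS = [
    "T_cur",
    "T_prev",
    "P_cue",
    "P_int",
    "P_joint",
    "PE_prev",
    "PE_cue",
    "PE_int",
    "PE_joint",
    "proactive_switch_demand",
    "confidence",
    "proactive_interference",
]


def internal_prediction_series(tasks, alpha: float, p0: float = 0.5) -> np.ndarray:
    """Delta-rule internal task prediction for each trial of a sequence.

    Parameters
    ----------
    tasks
        Binary (0/1) task sequence in chronological order.
    alpha
        Learning rate in [0, 1]; the weight of the previous trial relative
        to older history.
    p0
        Initial prediction before any task has been seen (default 0.5).

    Returns
    -------
    ndarray of the same length as ``tasks``; element ``i`` is the
    prediction *held on* trial ``i``, i.e. computed from trials before
    ``i`` only. The update happens after each trial.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    tasks = np.asarray(tasks, dtype=float)
    if tasks.size and not np.all(np.isin(tasks[np.isfinite(tasks)], (0.0, 1.0))):
        raise ValueError("tasks must be binary 0/1")
    p = np.empty(tasks.shape[0])
    cur = float(p0)
    for i, t in enumerate(tasks):
        p[i] = cur
        cur = (1.0 - alpha) * cur + alpha * t
    return p


def joint_prediction(p_int, p_cue, beta):
    """Convex combination ``(1 - beta) * p_int + beta * p_cue``.

    All arguments must lie in [0, 1]; arrays broadcast elementwise.
    """
    p_int = np.asarray(p_int, dtype=float)
    p_cue = np.asarray(p_cue, dtype=float)
    for name, val in (("p_int", p_int), ("p_cue", p_cue), ("beta", np.asarray(beta, float))):
        finite = np.atleast_1d(val)
        finite = finite[np.isfinite(finite)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    out = (1.0 - beta) * p_int + beta * p_cue
    return out if out.ndim else float(out)


def compute_model_variables(
    trials: pd.DataFrame,
    alpha: float,
    beta: float,
    p0: float = 0.5,
) -> pd.DataFrame:
    """Append all model-variable columns to a trial table.

    ``trials`` needs ``task`` (0/1) and ``precue`` columns in chronological
    order. Returns a copy with :data:`VARIABLE_COLUMNS` filled.
    """
    out = trials.reset_index(drop=True).copy()
    tasks = out["task"].to_numpy(dtype=float)
    out["T_cur"] = tasks
    t_prev = np.roll(tasks, 1)
    t_prev[0] = np.nan
    out["T_prev"] = t_prev
    out["P_cue"] = out["precue"].to_numpy(dtype=float)
    out["P_int"] = internal_prediction_series(tasks, alpha, p0)
    out["P_joint"] = joint_prediction(out["P_int"].to_numpy(), out["P_cue"].to_numpy(), beta)
    out = prediction_errors(out)
    out = demand_variables(out)
    return out


def prediction_errors(vars: pd.DataFrame) -> pd.DataFrame:
    """Fill the unsigned prediction-error columns ``PE_prev/cue/int/joint``."""
    out = vars.copy()
    t = out["T_cur"].to_numpy(dtype=float)
    out["PE_prev"] = np.abs(t - out["T_prev"].to_numpy(dtype=float))
    out["PE_cue"] = np.abs(t - out["P_cue"].to_numpy(dtype=float))
    out["PE_int"] = np.abs(t - out["P_int"].to_numpy(dtype=float))
    out["PE_joint"] = np.abs(t - out["P_joint"].to_numpy(dtype=float))
    return out


def demand_variables(vars: pd.DataFrame) -> pd.DataFrame:
    """Fill proactive switch demand, confidence and proactive interference."""
    out = vars.copy()
    out["proactive_switch_demand"] = np.abs(
        out["T_prev"].to_numpy(dtype=float) - out["P_joint"].to_numpy(dtype=float)
    )
    out["confidence"] = np.abs(out["P_joint"].to_numpy(dtype=float) - 0.5)
    out["proactive_interference"] = np.abs(
        out["P_int"].to_numpy(dtype=float) - out["P_cue"].to_numpy(dtype=float)
    )
    return out
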