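"""Per-subject RT model fitting and cross-validated model comparison.

Candidate models are GLMs predicting trial-wise RT from subsets of the
three unsigned prediction errors, always plus a constant:

=============== =========================
name            regressors
=============== =========================
joint_guidance  PE_cue, PE_int
max_benefit     PE_prev, PE_cue
full            PE_prev, PE_cue, PE_int
pe_prev         PE_prev
pe_cue          PE_cue
pe_int          PE_int
=============== =========================

PE coefficients are constrained non-negative (slower responses with
larger prediction error); the intercept is free. Color and motion trials
are fit separately to absorb the task main effect, and the two objectives
are summed. The learning rate ``alpha`` entering PE_int is estimated by
exhaustive grid search on [0, 1] (step 0.01, ties toward smaller alpha).
The cue reliance is ``beta = C_cue / (C_cue + C_int)`` with coefficients
summed over the two task fits.

Model comparison uses 3-fold cross-validation over chronological run
triplets; the per-subject score is ``N_test * ln(mean squared test
error)`` pooled over the three held-out folds — lower is better. Alpha is
re-estimated within each training set only.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variables import internal_prediction_series

__all__ = [
    "ModelSpec",
    "FitResult",
    "MODEL_SPECS",
    "preprocess_trials",
    "fit_nonneg_glm",
    "estimate_subject_fit",
    "crossval_score",
    "rt_gain",
    "split_half_beta",
]

#: Default exhaustive grid for the learning rate.
ALPHA_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)

#: Floor applied to a degenerate zero test error before taking the log.
MSE_FLOOR = 1e-12


class DegenerateSubjectError(ValueError):
    """Preprocessing removed every trial of a subject."""


@dataclass(frozen=True)
class ModelSpec:
    name: str
    regressors: tuple[str, ...]

    def __post_init__(self):
        if not self.regressors:
            raise ValueError("a model needs at least one PE regressor")
        bad = set(self.regressors) - {"PE_prev", "PE_cue", "PE_int"}
        if bad:
            raise ValueError(f"unknown regressors: {sorted(bad)}")


MODEL_SPECS: dict[str, ModelSpec] = {
    m.name: m
    for m in (
        ModelSpec("joint_guidance", ("PE_cue", "PE_int")),
        ModelSpec("max_benefit", ("PE_prev", "PE_cue")),
        ModelSpec("full", ("PE_prev", "PE_cue", "PE_int")),
        ModelSpec("pe_prev", ("PE_prev",)),
        ModelSpec("pe_cue", ("PE_cue",)),
        ModelSpec("pe_int", ("PE_int",)),
    )
}


@dataclass
class FitResult:
    subject: str
    model: str
    alpha_hat: float
    coefficients: dict  # {"motion"/"color": {"C_prev","C_cue","C_int","intercept"}}
    beta_hat: float  # NaN when undefined
    beta_defined: bool
    n_trials_used: int
    sse: float
    cv_score: float = field(default=np.nan)


def _as_spec(model) -> ModelSpec:
    if isinstance(model, ModelSpec):
        return model
    try:
        return MODEL_SPECS[model]
    except KeyError:
        raise KeyError(f"unknown model {model!r}; choose from {sorted(MODEL_SPECS)}")


def preprocess_trials(trials: pd.DataFrame, drop: bool = True) -> pd.DataFrame:
    """Remove error trials, then RT outliers beyond subject mean +/- 3 SD.

    Mean and SD are computed over the correct trials. With ``drop=False``
    excluded rows are kept but their ``rt`` is set to NaN, preserving the
    full task sequence for the internal-prediction recursion while still
    excluding the rows from any fit.
    """
    out = trials.reset_index(drop=True).copy()
    kept_parts = []
    for subject, sub in out.groupby("subject", sort=False):
        ok = sub["correct"].to_numpy(dtype=float) == 1.0
        rt = sub["rt"].to_numpy(dtype=float)
        ok &= np.isfinite(rt)
        if ok.sum() == 0:
            raise DegenerateSubjectError(f"no usable trials for subject {subject!r}")
        mean, sd = rt[ok].mean(), rt[ok].std(ddof=1)
        keep = ok & (np.abs(rt - mean) <= 3.0 * sd)
        if keep.sum() == 0:
            raise DegenerateSubjectError(f"no usable trials for subject {subject!r}")
        n_err, n_out = int((~ok).sum()), int((ok & ~keep).sum())
        if n_err or n_out:
            warnings.warn(
                f"subject {subject}: removed {n_err} error and {n_out} outlier trials",
                stacklevel=2,
            )
        kept_parts.append(keep)
    keep_all = np.concatenate(kept_parts)
    if drop:
        return out.loc[keep_all].reset_index(drop=True)
    out.loc[~keep_all, "rt"] = np.nan
    return out


def fit_nonneg_glm(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least squares with non-negative coefficients on all but the last column.

    ``X``'s final column is the (unconstrained) intercept. The convex QP is
    solved exactly by enumerating active sets of the constrained columns:
    for each subset clamped to zero, solve OLS on the rest; the feasible
    solution with the smallest SSE is the global optimum and satisfies the
    KKT conditions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] < X.shape[1]:
        raise ValueError("X must be 2-D with at least as many rows as columns")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        warnings.warn("rank-deficient design; returning minimum-norm solution", stacklevel=2)
    constrained = list(range(p - 1))
    best, best_sse = None, np.inf
    for clamp in itertools.chain.from_iterable(
        itertools.combinations(constrained, k) for k in range(len(constrained) + 1)
    ):
        free = [j for j in range(p) if j not in clamp]
        b_free, *_ = np.linalg.lstsq(X[:, free], y, rcond=None)
        b = np.zeros(p)
        b[free] = b_free
        if np.any(b[constrained] < -1e-10):
            continue
        resid = y - X @ b
        sse = float(resid @ resid)
        if sse < best_sse - 1e-15:
            best, best_sse = b, sse
    assert best is not None  # the all-clamped subset is always feasible
    best[constrained] = np.maximum(best[constrained], 0.0)
    return best


def _design(vars_df: pd.DataFrame, regressors: tuple[str, ...]) -> np.ndarray:
    cols = [vars_df[r].to_numpy(dtype=float) for r in regressors]
    cols.append(np.ones(len(vars_df)))
    return np.column_stack(cols)


def _pe_regressors(
    tasks: np.ndarray, precue: np.ndarray, alpha: float, p0: float
) -> pd.DataFrame:
    t_prev = np.roll(tasks, 1).astype(float)
    t_prev[0] = np.nan
    p_int = internal_prediction_series(tasks, alpha, p0)
    return pd.DataFrame(
        {
            "PE_prev": np.abs(tasks - t_prev),
            "PE_cue": np.abs(tasks - precue),
            "PE_int": np.abs(tasks - p_int),
        }
    )


def _fit_at_alpha(
    trials: pd.DataFrame,
    spec: ModelSpec,
    alpha: float,
    fit_mask: np.ndarray,
    p0: float,
) -> tuple[dict, float, pd.DataFrame]:
    """Fit both task GLMs at a fixed alpha; return (coefs, sse, regressors)."""
    tasks = trials["task"].to_numpy(dtype=float)
    regs = _pe_regressors(tasks, trials["precue"].to_numpy(dtype=float), alpha, p0)
    coefs: dict[str, dict[str, float]] = {}
    sse = 0.0
    for label, tval in (("motion", 0.0), ("color", 1.0)):
        rows = fit_mask & (tasks == tval)
        X = _design(regs.loc[rows], spec.regressors)
        yv = trials.loc[rows, "rt"].to_numpy(dtype=float)
        b = fit_nonneg_glm(X, yv)
        named = dict(zip(spec.regressors, b[:-1]))
        coefs[label] = {
            "C_prev": named.get("PE_prev", 0.0),
            "C_cue": named.get("PE_cue", 0.0),
            "C_int": named.get("PE_int", 0.0),
            "intercept": float(b[-1]),
        }
        resid = yv - X @ b
        sse += float(resid @ resid)
    return coefs, sse, regs


def estimate_subject_fit(
    trials: pd.DataFrame,
    model: str | ModelSpec = "joint_guidance",
    alpha_grid: np.ndarray = ALPHA_GRID,
    p0: float = 0.5,
) -> FitResult:
    """Fit one candidate model to one (preprocessed) subject.

    The first session trial (undefined predecessor) and rows with missing
    RT never enter the fit; the task sequence of all rows present feeds
    the internal-prediction recursion. Alpha is grid-searched only when
    the model contains PE_int.
    """
    spec = _as_spec(model)
    trials = trials.reset_index(drop=True)
    subject = str(trials["subject"].iloc[0]) if len(trials) else ""
    rt = trials["rt"].to_numpy(dtype=float)
    fit_mask = np.isfinite(rt)
    fit_mask[0] = False  # no T_prev on the first session trial
    if fit_mask.sum() < 4:
        raise DegenerateSubjectError(f"too few usable trials for subject {subject!r}")

    if "PE_int" in spec.regressors:
        best = None
        for alpha in alpha_grid:
            coefs, sse, _ = _fit_at_alpha(trials, spec, float(alpha), fit_mask, p0)
            if best is None or sse < best[1] - 1e-12:  # ties -> smaller alpha
                best = (float(alpha), sse, coefs)
        alpha_hat, sse, coefs = best
    else:
        coefs, sse, _ = _fit_at_alpha(trials, spec, 0.5, fit_mask, p0)
        alpha_hat = np.nan

    c_cue = coefs["motion"]["C_cue"] + coefs["color"]["C_cue"]
    c_int = coefs["motion"]["C_int"] + coefs["color"]["C_int"]
    has_beta_regs = bool({"PE_cue", "PE_int"} & set(spec.regressors))
    if has_beta_regs and (c_cue + c_int) > 0:
        beta_hat, beta_defined = c_cue / (c_cue + c_int), True
    else:
        beta_hat, beta_defined = np.nan, False
        warnings.warn(
            f"subject {subject}: beta undefined (C_cue = C_int = 0 or absent)",
            stacklevel=2,
        )
    return FitResult(
        subject=subject,
        model=spec.name,
        alpha_hat=alpha_hat,
        coefficients=coefs,
        beta_hat=beta_hat,
        beta_defined=beta_defined,
        n_trials_used=int(fit_mask.sum()),
        sse=sse,
    )


def _fold_runs(runs: np.ndarray) -> list[np.ndarray]:
    uniq = np.unique(runs)
    if len(uniq) % 3 != 0:
        raise ValueError(
            f"cross-validation needs a run count divisible by 3, got {len(uniq)}"
        )
    per = len(uniq) // 3
    return [uniq[i * per : (i + 1) * per] for i in range(3)]


def crossval_score(
    trials: pd.DataFrame,
    model: str | ModelSpec = "joint_guidance",
    alpha_grid: np.ndarray = ALPHA_GRID,
    p0: float = 0.5,
) -> float:
    """3-fold cross-validated score of one model for one subject.

    Folds are chronological run triplets. For each held-out fold, alpha
    and the coefficients are estimated on the training runs only; the
    score is ``N_test * ln(pooled mean squared test error)`` (natural
    log). Lower is better. A zero test error is floored at 1e-12 with a
    warning.
    """
    spec = _as_spec(model)
    trials = trials.reset_index(drop=True)
    runs = trials["run"].to_numpy()
    folds = _fold_runs(runs)
    tasks = trials["task"].to_numpy(dtype=float)
    rt = trials["rt"].to_numpy(dtype=float)
    usable = np.isfinite(rt)
    usable[0] = False

    sq_errors = []
    for held in folds:
        test_mask = usable & np.isin(runs, held)
        train_mask = usable & ~np.isin(runs, held)
        if "PE_int" in spec.regressors:
            best = None
            for alpha in alpha_grid:
                coefs, sse, regs = _fit_at_alpha(trials, spec, float(alpha), train_mask, p0)
                if best is None or sse < best[1] - 1e-12:
                    best = (float(alpha), sse, coefs, regs)
            _, _, coefs, regs = best
        else:
            coefs, _, regs = _fit_at_alpha(trials, spec, 0.5, train_mask, p0)
        for label, tval in (("motion", 0.0), ("color", 1.0)):
            rows = test_mask & (tasks == tval)
            if not rows.any():
                continue
            X = _design(regs.loc[rows], spec.regressors)
            c = coefs[label]
            b = np.array(
                [{"PE_prev": c["C_prev"], "PE_cue": c["C_cue"], "PE_int": c["C_int"]}[r] for r in spec.regressors]
                + [c["intercept"]]
            )
            sq_errors.append((rt[rows] - X @ b) ** 2)

    err = np.concatenate(sq_errors)
    mse = float(err.mean())
    if mse < MSE_FLOOR:
        warnings.warn("zero test error floored at 1e-12 before logging", stacklevel=2)
        mse = MSE_FLOOR
    return float(len(err) * np.log(mse))


def rt_gain(trials: pd.DataFrame) -> dict[str, float]:
    """Probabilistic expected RT acceleration from informative pre-cues.

    For each task, sums over non-neutral pre-cue levels the empirical
    probability of that (level, task) cell times the mean-RT difference
    between the uninformative 0.5 level (same task) and the cell.
    Positive values mean the subject responded faster under informative
    cues. Empty cells are skipped with a warning.
    """
    trials = trials.loc[np.isfinite(trials["rt"].to_numpy(dtype=float))]
    n_total = len(trials)
    gains = {}
    for label, tval in (("motion", 0), ("color", 1)):
        sub = trials[trials["task"] == tval]
        base = sub.loc[np.isclose(sub["precue"], 0.5), "rt"]
        if base.empty:
            warnings.warn(f"no 0.5-level {label} trials; gain undefined", stacklevel=2)
            gains[label] = np.nan
            continue
        baseline = float(base.mean())
        gain = 0.0
        for level, cell in sub.groupby("precue"):
            if np.isclose(level, 0.5):
                continue
            if cell.empty:  # pragma: no cover - groupby yields non-empty cells
                continue
            gain += len(cell) / n_total * (baseline - float(cell["rt"].mean()))
        gains[label] = gain
    return gains


def split_half_beta(
    trials: pd.DataFrame,
    model: str | ModelSpec = "joint_guidance",
    alpha_grid: np.ndarray = ALPHA_GRID,
) -> tuple[float, float]:
    """Cue reliance estimated independently from the first and last 3 runs.

    The internal-prediction recursion restarts at 0.5 within each half.
    """
    runs = np.unique(trials["run"].to_numpy())
    if len(runs) < 6:
        raise ValueError("split-half estimation needs at least 6 runs")
    first = trials[trials["run"].isin(runs[:3])].reset_index(drop=True)
    last = trials[trials["run"].isin(runs[-3:])].reset_index(drop=True)
    b1 = estimate_subject_fit(first, model, alpha_grid).beta_hat
    b2 = estimate_subject_fit(last, model, alpha_grid).beta_hat
    return b1, b2
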