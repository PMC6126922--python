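"""Descriptive group analyses: repeated-measures ANOVAs on RT and accuracy.

Two designs are covered, matching the standard behavioral workup of a
cued task-switching study:

* ``switch_cost_anova`` — 2 x 2 (task at trial i-lag x current task) on
  subject cell means, for lags 1..4. The interaction is the switch cost.
* ``precue_anova`` — 5 x 2 (pre-cue level x current task).

Both use classical within-subject sums of squares; for a 2 x 2 design
every effect F equals the squared paired t on the corresponding
difference scores. RT cells are computed after error/outlier removal;
accuracy cells from all trials. Subjects with an empty cell are excluded
with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import preprocess_trials

__all__ = ["rm_anova_2way", "switch_cost_anova", "precue_anova"]


def rm_anova_2way(cells: np.ndarray) -> dict:
    """Two-way fully within-subject ANOVA on a (subjects, A, B) cell array.

    Returns F, dfs and p for the two main effects and the interaction,
    each tested against its effect-by-subject error term.
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 3:
        raise ValueError("cells must be (subjects, A levels, B levels)")
    n, a, b = cells.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = cells.mean()
    subj = cells.mean(axis=(1, 2))
    A = cells.mean(axis=(0, 2))
    B = cells.mean(axis=(0, 1))
    AB = cells.mean(axis=0)
    iA = cells.mean(axis=2)  # subject x A
    iB = cells.mean(axis=1)  # subject x B

    def _f(ss_eff, df_eff, ss_err, df_err):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else np.inf)
        p = float(stats.f.sf(F, df_eff, df_err)) if np.isfinite(F) else 0.0
        return {"F": float(F), "df": (df_eff, df_err), "p": p}

    ss_a = n * b * float(((A - grand) ** 2).sum())
    ss_as = b * float(((iA - subj[:, None] - A[None, :] + grand) ** 2).sum())
    ss_b = n * a * float(((B - grand) ** 2).sum())
    ss_bs = a * float(((iB - subj[:, None] - B[None, :] + grand) ** 2).sum())
    ss_ab = n * float(((AB - A[:, None] - B[None, :] + grand) ** 2).sum())
    resid = (
        cells
        - iA[:, :, None]
        - iB[:, None, :]
        - AB[None, :, :]
        + subj[:, None, None]
        + A[None, :, None]
        + B[None, None, :]
        - grand
    )
    ss_abs = float((resid**2).sum())

    return {
        "A": _f(ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        "B": _f(ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        "AxB": _f(ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
        "cell_means": AB,
        "n_subjects": n,
    }


def _cell_means(
    cohort: pd.DataFrame,
    value: str,
    row_factor: np.ndarray,
    col_factor: np.ndarray,
    row_levels,
    col_levels,
) -> tuple[np.ndarray, list]:
    """Subject x row x col cell means; subjects with empty cells dropped."""
    subjects = list(dict.fromkeys(cohort["subject"]))
    keep, mats = [], []
    vals = cohort[value].to_numpy(dtype=float)
    subj_arr = cohort["subject"].to_numpy()
    finite = np.isfinite(vals) & np.isfinite(row_factor) & np.isfinite(col_factor)
    for s in subjects:
        m = np.full((len(row_levels), len(col_levels)), np.nan)
        sel_s = (subj_arr == s) & finite
        for i, rv in enumerate(row_levels):
            for j, cv in enumerate(col_levels):
                cell = vals[sel_s & np.isclose(row_factor, rv) & np.isclose(col_factor, cv)]
                if cell.size:
                    m[i, j] = cell.mean()
        if np.isnan(m).any():
            warnings.warn(f"subject {s}: empty design cell, excluded from ANOVA", stacklevel=3)
            continue
        keep.append(s)
        mats.append(m)
    if len(mats) < 2:
        raise ValueError("fewer than 2 subjects with complete cells")
    return np.stack(mats), keep


def _lagged_task(cohort: pd.DataFrame, lag: int) -> np.ndarray:
    out = np.full(len(cohort), np.nan)
    tasks = cohort["task"].to_numpy(dtype=float)
    for _, idx in cohort.groupby("subject", sort=False).indices.items():
        t = tasks[idx]
        lagged = np.full(t.shape, np.nan)
        lagged[lag:] = t[:-lag]
        out[idx] = lagged
    return out


def switch_cost_anova(cohort: pd.DataFrame, lag: int = 1) -> dict:
    """2 x 2 repeated-measures ANOVA (task at trial i-lag x current task).

    ``cohort`` is a multi-subject trial table with behavior filled.
    Returns per-measure (``rt``, ``accuracy``) ANOVA tables and group
    cell means, rows = previous task (motion, color), cols = current.
    """
    if lag not in (1, 2, 3, 4):
        raise ValueError("lag must be in 1..4")
    cohort = cohort.reset_index(drop=True)
    prev = _lagged_task(cohort, lag)
    cur = cohort["task"].to_numpy(dtype=float)

    out = {}
    rt_tab = preprocess_trials(cohort, drop=False)
    cells_rt, kept_rt = _cell_means(rt_tab, "rt", prev, cur, (0, 1), (0, 1))
    out["rt"] = rm_anova_2way(cells_rt) | {"subjects": kept_rt}
    cells_acc, kept_acc = _cell_means(cohort, "correct", prev, cur, (0, 1), (0, 1))
    out["accuracy"] = rm_anova_2way(cells_acc) | {"subjects": kept_acc}
    return out


def precue_anova(cohort: pd.DataFrame) -> dict:
    """5 x 2 repeated-measures ANOVA (pre-cue level x current task)."""
    cohort = cohort.reset_index(drop=True)
    levels = tuple(sorted(np.unique(cohort["precue"].to_numpy(dtype=float))))
    cue = cohort["precue"].to_numpy(dtype=float)
    cur = cohort["task"].to_numpy(dtype=float)
    out = {}
    rt_tab = preprocess_trials(cohort, drop=False)
    cells_rt, kept_rt = _cell_means(rt_tab, "rt", cue, cur, levels, (0, 1))
    out["rt"] = rm_anova_2way(cells_rt) | {"subjects": kept_rt, "levels": levels}
    cells_acc, kept_acc = _cell_means(cohort, "correct", cue, cur, levels, (0, 1))
    out["accuracy"] = rm_anova_2way(cells_acc) | {"subjects": kept_acc, "levels": levels}
    return out
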