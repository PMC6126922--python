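"""Searchlight encoding MVPA with permutation-based group inference.

For every voxel in the analysis mask, a *searchlight* collects the masked
voxels within a Euclidean radius (default 2 voxels, 33 voxels when the
neighborhood is complete). Within each searchlight a cross-validated
ridge regression predicts a model-variable time course from trial-wise
voxel activity: predictors are standardized on training statistics, the
intercept is unpenalized, held-out predictions are correlated with the
actual series, and the mean Fisher-z of the (3) fold correlations is the
searchlight's *encoding strength*, written at its center voxel.

Group inference is a voxelwise one-sample t-test against zero with
cluster-size family-wise-error correction from a sign-flip permutation
null of the maximum suprathreshold cluster size (26-neighborhood
connectivity by default). Specificity analyses include exclusive
masking, a linear-mixture search space over the two prediction sources,
and a random-reliance (beta~) permutation test with its distance-decay
summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from ._utils import as_rng, fisher_z

__all__ = [
    "SearchlightIndex",
    "EncodingMap",
    "ClusterInferenceResult",
    "PermutationResult",
    "build_searchlights",
    "encoding_strength",
    "whole_brain_encoding",
    "univariate_control",
    "group_cluster_inference",
    "exclusive_mask",
    "mixture_search_space",
    "pseudo_beta_permutation",
    "distance_decay",
]


# ---------------------------------------------------------------------------
# searchlight geometry


@dataclass(frozen=True)
class SearchlightIndex:
    """Sphere membership of every masked voxel.

    ``centers`` are voxel coordinates (S, 3); ``members`` is (S, m_max)
    of indices into the masked-voxel list, padded with -1; ``n_members``
    gives each searchlight's true size. ``flat_index`` maps masked-voxel
    order back to the 3D grid.
    """

    mask: np.ndarray
    radius: float
    centers: np.ndarray
    members: np.ndarray
    n_members: np.ndarray

    @property
    def n_searchlights(self) -> int:
        return self.centers.shape[0]


def build_searchlights(mask: np.ndarray, radius: float = 2.0) -> SearchlightIndex:
    """One searchlight per masked voxel; members within Euclidean radius."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask must be non-empty")
    if radius < 1:
        raise ValueError("radius must be at least 1 voxel")
    coords = np.argwhere(mask)  # (V, 3), C order
    flat = -np.ones(mask.shape, dtype=np.int64)
    flat[tuple(coords.T)] = np.arange(coords.shape[0])

    r = int(np.floor(radius))
    offs = np.array(
        [
            (dx, dy, dz)
            for dx in range(-r, r + 1)
            for dy in range(-r, r + 1)
            for dz in range(-r, r + 1)
            if dx * dx + dy * dy + dz * dz <= radius * radius
        ]
    )
    m_max = offs.shape[0]
    members = -np.ones((coords.shape[0], m_max), dtype=np.int64)
    shape = np.array(mask.shape)
    for j, off in enumerate(offs):
        pos = coords + off
        ok = np.all((pos >= 0) & (pos < shape), axis=1)
        idx = np.full(coords.shape[0], -1, dtype=np.int64)
        idx[ok] = flat[tuple(pos[ok].T)]
        members[:, j] = idx
    # compact: sort valid members first
    order = np.argsort(members == -1, axis=1, kind="stable")
    members = np.take_along_axis(members, order, axis=1)
    n_members = (members >= 0).sum(axis=1)
    members = members[:, : n_members.max()]
    return SearchlightIndex(
        mask=mask, radius=float(radius), centers=coords, members=members, n_members=n_members
    )


@dataclass
class EncodingMap:
    """3D encoding-strength map (Fisher-z at searchlight centers)."""

    values: np.ndarray
    mask: np.ndarray
    variable_name: str = ""
    subject: str = ""

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


# ---------------------------------------------------------------------------
# ridge encoding


def _fold_sets(fold_labels: np.ndarray) -> list[np.ndarray]:
    labels = np.unique(fold_labels)
    if labels.size < 2:
        raise ValueError("need at least 2 folds")
    return [fold_labels == lab for lab in labels]


def _encode_all(
    activity: np.ndarray,
    y: np.ndarray,
    fold_labels: np.ndarray,
    members: np.ndarray,
    ridge_penalty: float,
) -> np.ndarray:
    """Vectorized cross-validated ridge encoding for many searchlights.

    ``activity`` is trials x V (masked voxels); ``members`` is (S, m) of
    voxel indices padded with -1. Returns the per-searchlight mean
    Fisher-z over folds (NaN where every fold was skipped).
    """
    t, v = activity.shape
    s, m = members.shape
    # computations run in the dtype of `activity`; float32 input halves the
    # memory traffic of large Monte-Carlo runs at negligible cost to the maps
    dtype = np.dtype(activity.dtype) if activity.dtype in (np.float32, np.float64) else np.dtype(np.float64)
    # dummy all-zero voxel absorbs the padding: after standardization it
    # stays zero, its ridge weight is zero, so it never affects predictions
    pad = np.where(members < 0, v, members)
    flat_sub = (pad[:, :, None] * (v + 1) + pad[:, None, :]).ravel()
    zs = np.zeros((s,), dtype=np.float64)
    counts = np.zeros((s,), dtype=int)
    y = np.asarray(y, dtype=dtype)
    eye = (ridge_penalty * np.eye(m)).astype(dtype)

    for test in _fold_sets(fold_labels):
        train = ~test
        ytr = y[train]
        if np.all(ytr == ytr[0]):
            warnings.warn("constant variable in a training fold; fold skipped", stacklevel=3)
            continue
        a_tr = activity[train].astype(dtype, copy=False)
        mu = a_tr.mean(axis=0)
        sd = a_tr.std(axis=0)
        sd[sd == 0] = 1.0
        a_tr = (a_tr - mu) / sd
        a_te = (activity[test].astype(dtype, copy=False) - mu) / sd
        a_tr = np.concatenate([a_tr, np.zeros((a_tr.shape[0], 1), dtype=dtype)], axis=1)
        a_te = np.concatenate([a_te, np.zeros((a_te.shape[0], 1), dtype=dtype)], axis=1)
        yc = ytr - ytr.mean()

        cov = a_tr.T @ a_tr  # (V+1, V+1)
        xty = a_tr.T @ yc  # (V+1,)
        sub_cov = cov.ravel().take(flat_sub).reshape(s, m, m) + eye
        sub_xty = xty.take(pad)
        w = np.linalg.solve(sub_cov, sub_xty[..., None])[..., 0]  # (S, m)
        g_te = a_te[:, pad]  # (T_test, S, m) via fancy indexing
        pred = np.einsum("tsm,sm->st", g_te, w)
        yt = y[test]
        pc = pred - pred.mean(axis=1, keepdims=True)
        ytc = yt - yt.mean()
        denom = np.sqrt((pc**2).sum(axis=1) * (ytc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (pc @ ytc) / denom
        r = np.where(denom > 0, r, 0.0)
        zs += fisher_z(r)
        counts += 1

    out = np.full(s, np.nan)
    good = counts > 0
    out[good] = zs[good] / counts[good]
    return out


def encoding_strength(
    activity: np.ndarray,
    y: np.ndarray,
    fold_labels: np.ndarray,
    ridge_penalty: float = 1.0,
) -> float:
    """Cross-validated ridge encoding strength of one voxel set.

    ``activity`` is trials x voxels. Returns the mean Fisher-z of the
    held-out prediction/actual correlations across folds (NaN if every
    fold had a constant training variable).
    """
    activity = np.asarray(activity, dtype=float)
    members = np.arange(activity.shape[1])[None, :]
    return float(
        _encode_all(activity, np.asarray(y, float), np.asarray(fold_labels), members, ridge_penalty)[0]
    )


def _masked_activity(volumes: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """(x,y,z,trials) 4D array -> trials x masked-voxels matrix."""
    return np.ascontiguousarray(volumes[mask, :].T)


def whole_brain_encoding(
    volumes: np.ndarray,
    y: np.ndarray,
    index: SearchlightIndex,
    fold_labels: np.ndarray,
    split_by_task: np.ndarray | None = None,
    ridge_penalty: float = 1.0,
    variable_name: str = "",
    subject: str = "",
) -> EncodingMap:
    """Encoding strength of ``y`` in every searchlight of the mask.

    ``volumes`` is 4D (x, y, z, trial). If ``split_by_task`` (a binary
    per-trial array) is given, the analysis runs within each task's
    trials separately and the two z-maps are averaged — controlling for
    the task main effect.
    """
    act = _masked_activity(volumes, index.mask)
    y = np.asarray(y, dtype=float)
    fold_labels = np.asarray(fold_labels)
    if act.shape[0] != y.shape[0]:
        raise ValueError("volumes and variable series are misaligned")
    if split_by_task is None:
        z = _encode_all(act, y, fold_labels, index.members, ridge_penalty)
    else:
        task = np.asarray(split_by_task)
        zs = []
        for tval in np.unique(task):
            sel = task == tval
            zs.append(_encode_all(act[sel], y[sel], fold_labels[sel], index.members, ridge_penalty))
        z = np.nanmean(np.stack(zs), axis=0)
    values = np.full(index.mask.shape, np.nan)
    values[tuple(index.centers.T)] = z
    return EncodingMap(values=values, mask=index.mask, variable_name=variable_name, subject=subject)


def univariate_control(
    volumes: np.ndarray,
    y: np.ndarray,
    index: SearchlightIndex,
    fold_labels: np.ndarray,
    variable_name: str = "",
    subject: str = "",
) -> EncodingMap:
    """Univariate analogue: correlate searchlight-mean activity with ``y``.

    Within each fold (same 3-fold structure as the MVPA), the Pearson
    correlation between the searchlight's mean activity and the variable
    is Fisher-transformed; the fold-mean z is the univariate encoding
    strength. Sensitive only to mean-activity scaling, not to multivoxel
    patterns.
    """
    act = _masked_activity(volumes, index.mask)
    y = np.asarray(y, dtype=float)
    pad = np.where(index.members < 0, act.shape[1], index.members)
    act_pad = np.concatenate([act, np.zeros((act.shape[0], 1))], axis=1)
    sl_mean = act_pad[:, pad].sum(axis=2) / index.n_members  # trials x S
    zs = np.zeros(index.n_searchlights)
    counts = 0
    for test in _fold_sets(np.asarray(fold_labels)):
        yt = y[test]
        if np.all(yt == yt[0]):
            warnings.warn("constant variable in a fold; fold skipped", stacklevel=2)
            continue
        a = sl_mean[test]
        ac = a - a.mean(axis=0)
        yc = yt - yt.mean()
        denom = np.sqrt((ac**2).sum(axis=0) * (yc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (yc @ ac) / denom
        r = np.where(denom > 0, r, 0.0)
        zs += fisher_z(r)
        counts += 1
    z = zs / counts if counts else np.full(index.n_searchlights, np.nan)
    values = np.full(index.mask.shape, np.nan)
    values[tuple(index.centers.T)] = z
    return EncodingMap(values=values, mask=index.mask, variable_name=variable_name, subject=subject)


# ---------------------------------------------------------------------------
# group inference


@dataclass
class ClusterInferenceResult:
    tmap: np.ndarray
    threshold_t: float
    cluster_size_threshold: int
    clusters: pd.DataFrame
    labels: np.ndarray
    null_max_sizes: np.ndarray


def _stack_maps(maps) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(maps, np.ndarray):
        raise TypeError("pass a sequence of EncodingMap")
    mask = maps[0].mask
    data = np.stack([m.values[mask] for m in maps])
    return data, mask


def _tstat(data: np.ndarray) -> np.ndarray:
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd > 0, t, 0.0)


def _max_cluster_size(binary: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def group_cluster_inference(
    maps,
    voxel_p: float = 0.001,
    fwe_alpha: float = 0.05,
    n_perm: int = 1000,
    connectivity: int = 26,
    seed: int | None = None,
) -> ClusterInferenceResult:
    """One-sample group t-test with sign-flip cluster-size FWE correction.

    Each permutation flips the sign of every subject's whole map,
    preserving its magnitude; the null statistic is the largest cluster
    of voxels exceeding the one-sided ``voxel_p`` threshold. Observed
    clusters whose permutation p-value ``(1 + #{null >= size}) /
    (1 + n_perm)`` is at most ``fwe_alpha`` survive.
    """
    data, mask = _stack_maps(maps)
    n = data.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subjects for group inference")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations; FWE control will be coarse", stacklevel=2)
    data = np.nan_to_num(data, nan=0.0)
    structure = (
        np.ones((3, 3, 3), dtype=bool)
        if connectivity == 26
        else ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 2)
    )
    t_crit = float(stats.t.isf(voxel_p, n - 1))
    tvals = _tstat(data)
    tmap = np.full(mask.shape, np.nan)
    tmap[mask] = tvals

    rng = as_rng(seed)
    null_max = np.empty(n_perm, dtype=np.int64)
    grid = np.zeros(mask.shape, dtype=bool)
    for i in range(n_perm):
        signs = rng.choice((-1.0, 1.0), size=n)[:, None]
        tp = _tstat(data * signs)
        grid[:] = False
        grid[mask] = tp > t_crit
        null_max[i] = _max_cluster_size(grid, structure)

    grid[:] = False
    grid[mask] = tvals > t_crit
    labels, n_clusters = ndimage.label(grid, structure=structure)
    rows = []
    for c in range(1, n_clusters + 1):
        sel = labels == c
        size = int(sel.sum())
        p_fwe = float((1 + (null_max >= size).sum()) / (1 + n_perm))
        sel_flat = np.flatnonzero(sel.ravel())
        peak_flat = sel_flat[np.argmax(tmap.ravel()[sel_flat])]
        peak = np.unravel_index(peak_flat, mask.shape)
        rows.append(
            {
                "cluster": c,
                "size": size,
                "peak_t": float(np.nanmax(np.where(sel, tmap, -np.inf))),
                "peak_x": int(peak[0]),
                "peak_y": int(peak[1]),
                "peak_z": int(peak[2]),
                "p_fwe": p_fwe,
                "significant": p_fwe <= fwe_alpha,
            }
        )
    clusters = pd.DataFrame(
        rows, columns=["cluster", "size", "peak_t", "peak_x", "peak_y", "peak_z", "p_fwe", "significant"]
    )
    size_thr = int(np.quantile(null_max, 1 - fwe_alpha, method="higher")) if n_perm else 0
    surviving = np.isin(labels, clusters.loc[clusters["significant"], "cluster"].to_numpy())
    labels_out = np.where(surviving, labels, 0)
    return ClusterInferenceResult(
        tmap=tmap,
        threshold_t=t_crit,
        cluster_size_threshold=size_thr,
        clusters=clusters,
        labels=labels_out,
        null_max_sizes=null_max,
    )


def exclusive_mask(
    target_maps: list[EncodingMap],
    control_map_sets: list[list[EncodingMap]],
    voxel_p: float = 0.001,
) -> tuple[list[EncodingMap], np.ndarray]:
    """Remove target searchlights that significantly encode any control.

    For every control cohort, centers whose one-sample t (against 0,
    one-sided) is significant at ``voxel_p`` are set to NaN in all target
    maps before cluster inference. Returns the masked maps and the
    boolean 3D array of removed centers. Never adds centers.
    """
    tdata, mask = _stack_maps(target_maps)
    removed = np.zeros(mask.shape, dtype=bool)
    for control in control_map_sets:
        cdata, cmask = _stack_maps(control)
        if cmask.shape != mask.shape or not np.array_equal(cmask, mask):
            raise ValueError("control maps are not co-registered with the target")
        n = cdata.shape[0]
        t_crit = float(stats.t.isf(voxel_p, n - 1))
        tvals = _tstat(np.nan_to_num(cdata, nan=0.0))
        removed[mask] |= tvals > t_crit
    out = []
    for m in target_maps:
        vals = m.values.copy()
        vals[removed] = np.nan
        out.append(EncodingMap(values=vals, mask=mask, variable_name=m.variable_name, subject=m.subject))
    return out, removed


# ---------------------------------------------------------------------------
# reliance-specificity analyses


class _RoiEncoder:
    """Precomputed cross-validated ridge machinery for repeated y's.

    Factorizing the per-searchlight ridge systems once makes reliance
    permutations cheap: each new variable series costs one X'y product
    and one matrix-vector solve per searchlight and fold.
    """

    def __init__(self, activity, fold_labels, members, ridge_penalty=1.0):
        t, v = activity.shape
        self.folds = _fold_sets(np.asarray(fold_labels))
        self.members = members
        pad = np.where(members < 0, v, members)
        self.pad = pad
        m = members.shape[1]
        self.inv = []  # per fold: (S, m, m) inverse of (X'X + lam I)
        self.g_tr = []  # per fold: (T_train, S, m) standardized train data
        self.g_te = []  # per fold: (T_test, S, m)
        for test in self.folds:
            train = ~test
            a_tr = activity[train]
            mu, sd = a_tr.mean(axis=0), a_tr.std(axis=0)
            sd[sd == 0] = 1.0
            a_tr = np.concatenate([(a_tr - mu) / sd, np.zeros((train.sum(), 1))], axis=1)
            a_te = np.concatenate([(activity[test] - mu) / sd, np.zeros((test.sum(), 1))], axis=1)
            cov = a_tr.T @ a_tr
            sub = cov[pad[:, :, None], pad[:, None, :]] + ridge_penalty * np.eye(m)
            self.inv.append(np.linalg.inv(sub))
            self.g_tr.append(a_tr[:, pad])
            self.g_te.append(a_te[:, pad])

    def strength(self, y: np.ndarray) -> np.ndarray:
        """Per-searchlight mean Fisher-z for one variable series."""
        y = np.asarray(y, dtype=float)
        zs = np.zeros(self.members.shape[0])
        counts = 0
        for f, test in enumerate(self.folds):
            train = ~test
            ytr = y[train]
            if np.all(ytr == ytr[0]):
                continue
            yc = ytr - ytr.mean()
            xty = np.einsum("tsm,t->sm", self.g_tr[f], yc)
            w = np.einsum("smk,sk->sm", self.inv[f], xty)
            pred = np.einsum("tsm,sm->st", self.g_te[f], w)
            yt = y[test]
            pc = pred - pred.mean(axis=1, keepdims=True)
            ytc = yt - yt.mean()
            denom = np.sqrt((pc**2).sum(axis=1) * (ytc**2).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (pc @ ytc) / denom
            zs += fisher_z(np.where(denom > 0, r, 0.0))
            counts += 1
        return zs / counts if counts else np.full(self.members.shape[0], np.nan)


def _mixture_series(p_int, p_cue, beta, tasks=None, variable="P_joint"):
    pj = (1.0 - beta) * np.asarray(p_int, float) + beta * np.asarray(p_cue, float)
    if variable == "P_joint":
        return pj
    if variable == "PE_joint":
        if tasks is None:
            raise ValueError("PE_joint mixtures need the task series")
        return np.abs(np.asarray(tasks, float) - pj)
    raise ValueError(f"unsupported mixture variable {variable!r}")


def mixture_search_space(
    volumes_cohort: list[np.ndarray],
    p_cue_cohort: list[np.ndarray],
    p_int_cohort: list[np.ndarray],
    index: SearchlightIndex,
    fold_labels_cohort: list[np.ndarray],
    grid_step: float = 0.1,
    p_threshold: float = 0.01,
    ridge_penalty: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Searchlights encoding *any* linear mixture of P_cue and P_int.

    For each mixture weight on the beta grid {0, grid_step, ..., 1} the
    group t of the per-subject encoding strengths is computed per
    searchlight; the test statistic is the maximum over the grid
    (a stand-in for an F-map over the mixture family). Returns
    (boolean selection over searchlights, max-t per searchlight);
    selected searchlights exceed the one-sided uncorrected
    ``p_threshold`` critical t.
    """
    encoders = [
        _RoiEncoder(_masked_activity(v, index.mask), fl, index.members, ridge_penalty)
        for v, fl in zip(volumes_cohort, fold_labels_cohort)
    ]
    betas = np.round(np.arange(0.0, 1.0 + 1e-9, grid_step), 10)
    n = len(encoders)
    max_t = np.full(index.n_searchlights, -np.inf)
    for b in betas:
        zs = np.stack(
            [
                enc.strength(_mixture_series(pi, pc, b))
                for enc, pi, pc in zip(encoders, p_int_cohort, p_cue_cohort)
            ]
        )
        max_t = np.maximum(max_t, _tstat(np.nan_to_num(zs, nan=0.0)))
    t_crit = float(stats.t.isf(p_threshold, n - 1))
    return max_t > t_crit, max_t


@dataclass
class PermutationResult:
    """Random-reliance permutation outcome.

    ``p_value = (1 + #{null >= observed}) / (1 + n_perm)``.
    """

    beta_tilde: np.ndarray  # (n_perm, n_subjects)
    null_stats: np.ndarray
    observed: float
    p_value: float
    statistic: str
    behavioral_betas: np.ndarray
    null_strengths: np.ndarray  # group-mean ROI strength per draw


def pseudo_beta_permutation(
    volumes_cohort: list[np.ndarray],
    p_cue_cohort: list[np.ndarray],
    p_int_cohort: list[np.ndarray],
    behavioral_betas: np.ndarray,
    roi_centers: np.ndarray,
    index: SearchlightIndex,
    fold_labels_cohort: list[np.ndarray],
    n_perm: int = 1000,
    statistic: str = "roi_mean",
    sampler=None,
    seed: int | None = None,
    tasks_cohort: list[np.ndarray] | None = None,
    variable: str = "P_joint",
    voxel_p: float = 0.001,
    ridge_penalty: float = 1.0,
) -> PermutationResult:
    """Specificity test of the behaviorally derived cue reliances.

    Each permutation draws a random reliance ``beta~`` per subject
    (default sampler: independent Uniform(0, 1)), forms the
    corresponding pseudo joint prediction, and recomputes the ROI
    encoding. The null statistic is either the group-mean ROI encoding
    strength (``roi_mean``) or the largest cluster of centers
    significant at ``voxel_p`` within the ROI (``max_cluster``). The
    observed statistic uses the behavioral betas.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations; p-value resolution is coarse", stacklevel=2)
    if statistic not in ("roi_mean", "max_cluster"):
        raise ValueError("statistic must be 'roi_mean' or 'max_cluster'")
    roi_centers = np.asarray(roi_centers)
    mask_flat = np.zeros(index.mask.shape, dtype=bool)
    mask_flat[tuple(np.asarray(index.centers[roi_centers]).T)] = True
    if (mask_flat & ~index.mask).any():
        raise ValueError("ROI centers must lie inside the mask")

    rng = as_rng(seed)
    n_subj = len(volumes_cohort)
    behavioral_betas = np.asarray(behavioral_betas, dtype=float)
    encoders = [
        _RoiEncoder(
            _masked_activity(v, index.mask), fl, index.members[roi_centers], ridge_penalty
        )
        for v, fl in zip(volumes_cohort, fold_labels_cohort)
    ]
    tasks_cohort = tasks_cohort or [None] * n_subj
    structure = np.ones((3, 3, 3), dtype=bool)
    roi_coords = index.centers[roi_centers]

    def _cohort_z(betas):
        return np.stack(
            [
                enc.strength(_mixture_series(pi, pc, b, tk, variable))
                for enc, pi, pc, b, tk in zip(
                    encoders, p_int_cohort, p_cue_cohort, betas, tasks_cohort
                )
            ]
        )

    def _stat(zs):
        if statistic == "roi_mean":
            return float(np.nanmean(zs))
        t_crit = float(stats.t.isf(voxel_p, n_subj - 1))
        sig = _tstat(np.nan_to_num(zs, nan=0.0)) > t_crit
        grid = np.zeros(index.mask.shape, dtype=bool)
        grid[tuple(roi_coords[sig].T)] = True
        return float(_max_cluster_size(grid, structure))

    if sampler is None:
        sampler = lambda rng, n: rng.uniform(0.0, 1.0, n)

    obs_z = _cohort_z(behavioral_betas)
    observed = _stat(obs_z)
    beta_tilde = np.empty((n_perm, n_subj))
    null_stats = np.empty(n_perm)
    null_strengths = np.empty(n_perm)
    for i in range(n_perm):
        bt = np.asarray(sampler(rng, n_subj), dtype=float)
        beta_tilde[i] = bt
        zs = _cohort_z(bt)
        null_stats[i] = _stat(zs)
        null_strengths[i] = float(np.nanmean(zs))
    p = float((1 + (null_stats >= observed).sum()) / (1 + n_perm))
    return PermutationResult(
        beta_tilde=beta_tilde,
        null_stats=null_stats,
        observed=observed,
        p_value=p,
        statistic=statistic,
        behavioral_betas=behavioral_betas,
        null_strengths=null_strengths,
    )


def distance_decay(
    behavioral_betas: np.ndarray,
    beta_tilde: np.ndarray,
    strengths: np.ndarray,
) -> tuple[float, float]:
    """Correlation between reliance distance and encoding strength.

    For each permutation draw, the Euclidean distance of the sampled
    reliance vector from the behavioral one is correlated (Pearson) with
    the draw's group-mean encoding strength. A negative r says encoding
    decays as the reliances move away from the behavioral estimates —
    the behavioral betas sit at a local maximum. Returns (r, p).
    """
    beta_tilde = np.asarray(beta_tilde, dtype=float)
    strengths = np.asarray(strengths, dtype=float)
    if beta_tilde.shape[0] < 100:
        raise ValueError("need at least 100 permutation draws")
    d = np.linalg.norm(beta_tilde - np.asarray(behavioral_betas, float)[None, :], axis=1)
    if np.allclose(d, d[0]):
        raise ValueError("degenerate distances: all draws equidistant from the behavioral betas")
    r, p = stats.pearsonr(d, strengths)
    return float(r), float(p)
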