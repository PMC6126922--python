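"""Searchlight geometry, ridge encoding, group inference and specificity."""

import numpy as np
import pytest
from scipy import stats

import taskpred as tp
from taskpred._utils import fisher_z
from taskpred.searchlight import EncodingMap


def _maps_from(values_list, mask):
    out = []
    for v in values_list:
        vals = np.full(mask.shape, np.nan)
        vals[mask] = v
        out.append(EncodingMap(values=vals, mask=mask))
    return out


# ---------------------------------------------------------------------------
# geometry


def test_interior_searchlight_has_33_members():
    mask = np.ones((9, 9, 9), dtype=bool)
    idx = tp.build_searchlights(mask, 2.0)
    center = np.all(idx.centers == 4, axis=1)
    assert idx.n_members[center][0] == 33
    # oracle: enumerate integer offsets with squared norm <= 4
    count = sum(
        1
        for dx in range(-2, 3)
        for dy in range(-2, 3)
        for dz in range(-2, 3)
        if dx * dx + dy * dy + dz * dz <= 4
    )
    assert count == 33


def test_single_voxel_mask():
    mask = np.zeros((5, 5, 5), dtype=bool)
    mask[2, 2, 2] = True
    idx = tp.build_searchlights(mask, 2.0)
    assert idx.n_searchlights == 1
    assert idx.n_members[0] == 1


def test_members_respect_mask():
    mask = tp.sphere_mask((10, 10, 10), (5, 5, 5), 3.0)
    idx = tp.build_searchlights(mask, 2.0)
    flat_ok = np.flatnonzero(mask.ravel())
    coords = np.argwhere(mask)
    for s in range(idx.n_searchlights):
        mem = idx.members[s][idx.members[s] >= 0]
        assert np.all(mem < coords.shape[0])
        d = np.linalg.norm(coords[mem] - idx.centers[s], axis=1)
        assert np.all(d <= 2.0 + 1e-9)


def test_radius_validation():
    with pytest.raises(ValueError):
        tp.build_searchlights(np.ones((4, 4, 4), bool), 0.5)
    with pytest.raises(ValueError):
        tp.build_searchlights(np.zeros((4, 4, 4), bool), 2.0)


# ---------------------------------------------------------------------------
# encoding strength


def test_vanishing_penalty_matches_ols_oracle():
    rng = np.random.default_rng(0)
    act = rng.normal(size=(30, 3))
    y = act @ np.array([0.5, -0.3, 0.2]) + rng.normal(0, 0.5, 30)
    folds = np.repeat([0, 1, 2], 10)
    got = tp.encoding_strength(act, y, folds, ridge_penalty=1e-10)
    # OLS predictions are invariant to the standardization reparameterization
    zs = []
    for f in range(3):
        test = folds == f
        Xtr = np.column_stack([act[~test], np.ones((~test).sum())])
        b, *_ = np.linalg.lstsq(Xtr, y[~test], rcond=None)
        Xte = np.column_stack([act[test], np.ones(test.sum())])
        pred = Xte @ b
        zs.append(fisher_z(stats.pearsonr(pred, y[test])[0]))
    assert got == pytest.approx(np.mean(zs), abs=1e-8)


def test_matches_sklearn_ridge_oracle():
    sklearn = pytest.importorskip("sklearn.linear_model")
    rng = np.random.default_rng(1)
    act = rng.normal(size=(60, 5))
    y = act @ rng.normal(size=5) + rng.normal(0, 1, 60)
    folds = np.repeat([0, 1, 2], 20)
    lam = 2.5
    got = tp.encoding_strength(act, y, folds, ridge_penalty=lam)
    zs = []
    for f in range(3):
        test = folds == f
        mu, sd = act[~test].mean(axis=0), act[~test].std(axis=0)
        Xtr = (act[~test] - mu) / sd
        Xte = (act[test] - mu) / sd
        model = sklearn.Ridge(alpha=lam, fit_intercept=True)
        model.fit(Xtr, y[~test])
        pred = model.predict(Xte)
        zs.append(fisher_z(stats.pearsonr(pred, y[test])[0]))
    assert got == pytest.approx(np.mean(zs), abs=1e-8)


def test_noiseless_encoding_saturates():
    rng = np.random.default_rng(2)
    w = rng.normal(size=4)
    y = rng.normal(size=45)
    act = np.outer(y, w)
    folds = np.repeat([0, 1, 2], 15)
    z = tp.encoding_strength(act, y, folds, ridge_penalty=1e-8)
    assert np.tanh(z) > 0.999999


def test_null_encoding_is_unbiased():
    """Independent y: mean z over 500 seeded datasets within 3 SE of 0."""
    rng = np.random.default_rng(3)
    zs = []
    for _ in range(500):
        act = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        zs.append(tp.encoding_strength(act, y, np.repeat([0, 1, 2], 10)))
    zs = np.asarray(zs)
    se = zs.std(ddof=1) / np.sqrt(len(zs))
    assert abs(zs.mean()) < 3 * se


def test_affine_invariance_of_variable():
    rng = np.random.default_rng(4)
    act = rng.normal(size=(30, 4))
    y = rng.normal(size=30)
    folds = np.repeat([0, 1, 2], 10)
    a = tp.encoding_strength(act, y, folds)
    b = tp.encoding_strength(act, 3.0 + 2.0 * y, folds)
    assert a == pytest.approx(b, abs=1e-9)


def test_constant_training_variable_skips_fold():
    rng = np.random.default_rng(5)
    act = rng.normal(size=(30, 4))
    y = np.zeros(30)
    with pytest.warns(UserWarning, match="constant"):
        z = tp.encoding_strength(act, y, np.repeat([0, 1, 2], 10))
    assert np.isnan(z)


# ---------------------------------------------------------------------------
# whole-brain maps and univariate control


@pytest.fixture(scope="module")
def small_geometry():
    mask = tp.sphere_mask((12, 12, 12), (6, 6, 6), 5.0)
    return mask, tp.build_searchlights(mask, 2.0)


def test_whole_brain_embedding_detected(small_geometry):
    mask, index = small_geometry
    rng = np.random.default_rng(6)
    y = rng.normal(size=60)
    folds = np.repeat([0, 1, 2], 20)
    roi = tp.sphere_mask(mask.shape, (8, 6, 6), 1.5) & mask
    vols = np.zeros(mask.shape + (60,))
    vols[mask, :] = rng.normal(size=(int(mask.sum()), 60))
    w = rng.normal(size=int(roi.sum()))
    vols[roi, :] += 2.0 * np.outer(w, y)
    emap = tp.whole_brain_encoding(vols, y, index, folds)
    roi_z = emap.values[roi]
    # searchlights near the ROI see its voxels; compare only distant centers
    far = mask & ~tp.sphere_mask(mask.shape, (8, 6, 6), 3.6)
    rest_z = emap.values[far]
    assert np.nanmean(roi_z) > 0.5
    assert abs(np.nanmean(rest_z)) < 0.1


def test_split_by_task_close_to_unsplit(small_geometry):
    mask, index = small_geometry
    rng = np.random.default_rng(7)
    y = rng.normal(size=60)
    task = np.tile([0, 1], 30)
    folds = np.repeat([0, 1, 2], 20)
    roi = tp.sphere_mask(mask.shape, (8, 6, 6), 1.5) & mask
    vols = np.zeros(mask.shape + (60,))
    vols[mask, :] = rng.normal(size=(int(mask.sum()), 60))
    vols[roi, :] += 1.5 * np.outer(rng.normal(size=int(roi.sum())), y)
    a = tp.whole_brain_encoding(vols, y, index, folds)
    b = tp.whole_brain_encoding(vols, y, index, folds, split_by_task=task)
    assert np.nanmean(b.values[roi]) > 0.3
    assert np.nanmean(a.values[roi]) == pytest.approx(np.nanmean(b.values[roi]), abs=0.35)


def test_univariate_control_distinguishes_mean_from_pattern(small_geometry):
    mask, index = small_geometry
    rng = np.random.default_rng(8)
    y = rng.normal(size=60)
    folds = np.repeat([0, 1, 2], 20)
    roi = tp.sphere_mask(mask.shape, (6, 6, 6), 1.5) & mask
    nroi = int(roi.sum())
    # uniform scaling: every ROI voxel goes up with y -> univariate signal
    vols_uni = np.zeros(mask.shape + (60,))
    vols_uni[mask, :] = 0.1 * rng.normal(size=(int(mask.sum()), 60))
    vols_uni[roi, :] += np.outer(np.ones(nroi), y)
    # zero-sum pattern: multivoxel signal with no mean-activity component
    w = rng.normal(size=nroi)
    w -= w.mean()
    vols_pat = np.zeros(mask.shape + (60,))
    vols_pat[mask, :] = 0.1 * rng.normal(size=(int(mask.sum()), 60))
    vols_pat[roi, :] += np.outer(w, y)

    center_lin = np.flatnonzero(np.all(index.centers == 6, axis=1))[0]
    cx, cy, cz = index.centers[center_lin]
    uni_u = tp.univariate_control(vols_uni, y, index, folds).values[cx, cy, cz]
    uni_m = tp.whole_brain_encoding(vols_uni, y, index, folds).values[cx, cy, cz]
    pat_u = tp.univariate_control(vols_pat, y, index, folds).values[cx, cy, cz]
    pat_m = tp.whole_brain_encoding(vols_pat, y, index, folds).values[cx, cy, cz]
    assert uni_u > 1.0 and uni_m > 1.0  # both see the uniform signal
    assert pat_m > 1.0  # MVPA sees the pattern
    assert abs(pat_u) < 0.3  # univariate control does not


def test_pure_noise_maps_are_near_zero(small_geometry):
    mask, index = small_geometry
    rng = np.random.default_rng(9)
    vols = np.zeros(mask.shape + (60,))
    vols[mask, :] = rng.normal(size=(int(mask.sum()), 60))
    y = rng.normal(size=60)
    folds = np.repeat([0, 1, 2], 20)
    m = tp.whole_brain_encoding(vols, y, index, folds)
    u = tp.univariate_control(vols, y, index, folds)
    assert abs(np.nanmean(m.masked_values())) < 0.1
    assert abs(np.nanmean(u.masked_values())) < 0.1


# ---------------------------------------------------------------------------
# group inference, exclusive masking


def test_group_inference_recovers_embedded_region(small_geometry):
    mask, index = small_geometry
    rng = np.random.default_rng(10)
    roi = tp.sphere_mask(mask.shape, (7, 6, 6), 1.5) & mask
    v = int(mask.sum())
    maps = []
    for s in range(8):
        z = 0.05 * rng.normal(size=v)
        z[roi[mask]] += 1.0
        maps.append(z)
    res = tp.group_cluster_inference(_maps_from(maps, mask), n_perm=300, seed=0)
    assert res.clusters["significant"].any()
    assert ((res.labels > 0) & roi).sum() == roi.sum()


def test_group_inference_degenerate_constant_maps(small_geometry):
    mask, index = small_geometry
    v = int(mask.sum())
    maps = [np.ones(v)] * 4 + [-np.ones(v)]
    res = tp.group_cluster_inference(_maps_from(maps, mask), n_perm=100, seed=1)
    assert len(res.clusters) == 0  # zero-variance voxels guarded, t set to 0


def test_group_inference_validation(small_geometry):
    mask, _ = small_geometry
    v = int(mask.sum())
    with pytest.raises(ValueError):
        tp.group_cluster_inference(_maps_from([np.ones(v)] * 3, mask))
    with pytest.warns(UserWarning, match="permutations"):
        tp.group_cluster_inference(_maps_from([np.random.default_rng(2).normal(size=v) for _ in range(6)], mask), n_perm=50, seed=2)


def test_exclusive_mask_set_difference(small_geometry):
    mask, _ = small_geometry
    v = int(mask.sum())
    rng = np.random.default_rng(11)
    region_a = tp.sphere_mask(mask.shape, (6, 6, 6), 2.0) & mask
    region_b = tp.sphere_mask(mask.shape, (8, 6, 6), 2.0) & mask
    targets = [rng.normal(0, 0.05, v) + region_a[mask] for _ in range(8)]
    controls = [rng.normal(0, 0.05, v) + region_b[mask] for _ in range(8)]
    tmaps = _maps_from(targets, mask)
    cmaps = _maps_from(controls, mask)
    masked, removed = tp.exclusive_mask(tmaps, [cmaps], voxel_p=0.001)
    # removal is exactly the control-significant set, independently recomputed
    cdata = np.stack(controls)
    tvals = cdata.mean(0) / (cdata.std(0, ddof=1) / np.sqrt(8))
    expect = tvals > stats.t.isf(0.001, 7)
    assert np.array_equal(removed[mask], expect)
    for m, t0 in zip(masked, tmaps):
        assert np.isnan(m.values[removed]).all()
        keep = mask & ~removed
        np.testing.assert_array_equal(m.values[keep], t0.values[keep])


def test_exclusive_mask_extremes(small_geometry):
    mask, _ = small_geometry
    v = int(mask.sum())
    rng = np.random.default_rng(12)
    targets = _maps_from([rng.normal(size=v) for _ in range(6)], mask)
    everywhere = _maps_from([np.full(v, 5.0) + 0.01 * rng.normal(size=v) for _ in range(6)], mask)
    masked, removed = tp.exclusive_mask(targets, [everywhere])
    assert removed[mask].all()
    assert all(np.isnan(m.masked_values()).all() for m in masked)
    nowhere = _maps_from([rng.normal(size=v) - 5.0 for _ in range(6)], mask)
    masked2, removed2 = tp.exclusive_mask(targets, [nowhere])
    assert not removed2.any()
    for m, t0 in zip(masked2, targets):
        np.testing.assert_array_equal(m.masked_values(), t0.masked_values())


# ---------------------------------------------------------------------------
# mixture search space and reliance permutations


def _embedded_cohort(mask, index, variable_beta, n_subj=6, snr=1.5, seed=13):
    """Tiny cohort with an ROI encoding a beta-mixture of P_cue and P_int."""
    rng = np.random.default_rng(seed)
    roi = tp.sphere_mask(mask.shape, (7, 6, 6), 1.5) & mask
    vols_l, pc_l, pi_l, folds_l = [], [], [], []
    for s in range(n_subj):
        pc = rng.choice([0.2, 0.4, 0.5, 0.6, 0.8], 60)
        pi = np.clip(0.5 + np.cumsum(rng.normal(0, 0.1, 60)) % 0.5, 0, 1)
        y = (1 - variable_beta) * pi + variable_beta * pc
        y = (y - y.mean()) / y.std()
        vols = np.zeros(mask.shape + (60,))
        vols[mask, :] = rng.normal(size=(int(mask.sum()), 60))
        vols[roi, :] += snr * np.outer(rng.normal(size=int(roi.sum())), y)
        vols_l.append(vols)
        pc_l.append(pc)
        pi_l.append(pi)
        folds_l.append(np.repeat([0, 1, 2], 20))
    return roi, vols_l, pc_l, pi_l, folds_l


def test_mixture_search_space_includes_pure_cue_region(small_geometry):
    mask, index = small_geometry
    roi, vols_l, pc_l, pi_l, folds_l = _embedded_cohort(mask, index, variable_beta=1.0)
    selected, max_t = tp.mixture_search_space(vols_l, pc_l, pi_l, index, folds_l)
    roi_lin = roi[tuple(index.centers.T)]
    assert selected[roi_lin].mean() > 0.8  # ROI centers included
    # searchlights within reach of ROI voxels (center distance <= r_roi +
    # r_searchlight) legitimately see signal; judge only distant centers
    far = np.linalg.norm(index.centers - np.array([7, 6, 6]), axis=1) > 3.7
    assert selected[far].mean() < 0.15  # noise centers mostly excluded


def test_pseudo_beta_permutation_detects_behavioral_reliance(small_geometry):
    mask, index = small_geometry
    beta_true = 0.3
    roi, vols_l, pc_l, pi_l, folds_l = _embedded_cohort(mask, index, variable_beta=beta_true)
    roi_lin = np.flatnonzero(roi[tuple(index.centers.T)])
    betas = np.full(len(vols_l), beta_true)
    res = tp.pseudo_beta_permutation(
        vols_l, pc_l, pi_l, betas, roi_lin, index, folds_l, n_perm=99, seed=0
    )
    assert res.p_value <= 0.05
    assert res.observed >= np.quantile(res.null_stats, 0.9)


def test_pseudo_beta_validation(small_geometry):
    mask, index = small_geometry
    roi, vols_l, pc_l, pi_l, folds_l = _embedded_cohort(mask, index, 0.3, n_subj=2)
    roi_lin = np.flatnonzero(roi[tuple(index.centers.T)])
    with pytest.raises(ValueError):
        tp.pseudo_beta_permutation(
            vols_l, pc_l, pi_l, np.array([0.3, 0.3]), roi_lin, index, folds_l, n_perm=0
        )


def test_distance_decay_constructed_ordering():
    rng = np.random.default_rng(14)
    betas = np.full(6, 0.3)
    bt = rng.uniform(0, 1, size=(150, 6))
    d = np.linalg.norm(bt - betas, axis=1)
    strengths = -d  # strictly ordered by distance
    r, p = tp.distance_decay(betas, bt, strengths)
    assert r == pytest.approx(-1.0, abs=1e-12)
    with pytest.raises(ValueError):
        tp.distance_decay(betas, bt[:50], strengths[:50])
    with pytest.raises(ValueError):
        tp.distance_decay(betas, np.tile(bt[0], (150, 1)), strengths)
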