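"""End-to-end synthetic-study pipeline.

``run_pipeline`` chains the full workflow on a simulated cohort:

    design -> behavior -> per-subject model fits -> cross-validated
    model comparison -> Bayesian model selection -> synthetic volumes ->
    searchlight encoding + group cluster inference -> random-reliance
    permutation

writing every intermediate artifact plus a machine-readable
``summary.json``. A single top-level seed deterministically spawns one
child seed per stage, so the whole bundle is reproducible while stages
stay independent.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._utils import spawn_seeds
from .bms import protected_exceedance, scores_to_log_evidence
from .cohort import PopulationSpec, sample_cohort, simulate_behavior
from .design import DesignConfig, generate_trial_sequence
from .fitting import (
    ALPHA_GRID,
    MODEL_SPECS,
    crossval_score,
    estimate_subject_fit,
    preprocess_trials,
)
from .io import write_mask, write_trials, write_volumes
from .searchlight import (
    build_searchlights,
    distance_decay,
    group_cluster_inference,
    pseudo_beta_permutation,
    whole_brain_encoding,
)
from .variables import compute_model_variables
from .volumes import EncodingSpec, ROIEncoding, VolumeGeometry, simulate_volumes, sphere_mask

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "config_from_dict"]

log = logging.getLogger("taskpred")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass(frozen=True)
class FittingConfig:
    models: tuple[str, ...] = tuple(MODEL_SPECS)
    alpha_step: float = 0.01


@dataclass(frozen=True)
class BmsConfig:
    n_samples: int = 100_000
    prior_alpha: float = 1.0


@dataclass(frozen=True)
class VolumesConfig:
    enabled: bool = True
    shape: tuple[int, int, int] = (16, 16, 16)
    mask_radius: float = 6.0
    roi_radius: float = 2.0
    roi_offset: tuple[int, int, int] = (2, 0, 0)
    snr: float = 0.5
    variable: str = "P_joint"
    save_nifti: bool = True


@dataclass(frozen=True)
class MvpaConfig:
    radius: float = 2.0
    ridge_penalty: float = 1.0
    voxel_p: float = 0.001
    fwe_alpha: float = 0.05
    n_perm: int = 500
    pseudo_n_perm: int = 100
    statistic: str = "roi_mean"


@dataclass(frozen=True)
class PipelineConfig:
    n_subjects: int = 6
    seed: int = 0
    design: DesignConfig = field(default_factory=DesignConfig)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    fitting: FittingConfig = field(default_factory=FittingConfig)
    bms: BmsConfig = field(default_factory=BmsConfig)
    volumes: VolumesConfig = field(default_factory=VolumesConfig)
    mvpa: MvpaConfig = field(default_factory=MvpaConfig)


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if isinstance(val, list):
            val = tuple(val)
        coerced[f.name] = val
    return cls(**coerced)


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a validated PipelineConfig from a nested dict (YAML/JSON)."""
    data = dict(data or {})
    nested = {
        "design": DesignConfig,
        "population": PopulationSpec,
        "fitting": FittingConfig,
        "bms": BmsConfig,
        "volumes": VolumesConfig,
        "mvpa": MvpaConfig,
    }
    kwargs = {}
    for key, cls in nested.items():
        if key in data:
            kwargs[key] = _build(cls, data.pop(key))
    top = {f.name for f in dataclasses.fields(PipelineConfig)} - set(nested)
    unknown = set(data) - top
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs.update(data)
    return PipelineConfig(**kwargs)


def _fold_labels_from_runs(runs: np.ndarray) -> np.ndarray:
    uniq = np.unique(runs)
    per = len(uniq) // 3
    labels = np.zeros(len(runs), dtype=int)
    for i in range(3):
        labels[np.isin(runs, uniq[i * per : (i + 1) * per])] = i
    return labels


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full synthetic study; returns the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = spawn_seeds(config.seed, 6)
    summary: dict = {
        "taskpred_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_subjects": config.n_subjects,
    }
    log.info("pipeline start: %d subjects, seed %d", config.n_subjects, config.seed)

    def _stage(name):
        log.info("stage: %s", name)

    alpha_grid = np.round(
        np.arange(0.0, 1.0 + 1e-9, config.fitting.alpha_step), 10
    )

    # --- simulate ---------------------------------------------------------
    try:
        _stage("simulate")
        cohort_params = sample_cohort(config.n_subjects, config.population, seeds[0])
        sub_seeds = spawn_seeds(seeds[1], 2 * config.n_subjects)
        tables = []
        for i, params in enumerate(cohort_params):
            sid = f"sub-{i + 1:02d}"
            trials = generate_trial_sequence(config.design, sub_seeds[2 * i], subject=sid)
            trials = simulate_behavior(trials, params, sub_seeds[2 * i + 1])
            write_trials(trials, out / f"{sid}_trials.tsv")
            tables.append(trials)
        summary["true_params"] = [
            {"subject": f"sub-{i + 1:02d}", "alpha": p.alpha, "beta": p.beta}
            for i, p in enumerate(cohort_params)
        ]
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("simulate", exc) from exc

    # --- fit --------------------------------------------------------------
    try:
        _stage("fit")
        fits = []
        for trials in tables:
            pre = preprocess_trials(trials, drop=False)
            fits.append(estimate_subject_fit(pre, "joint_guidance", alpha_grid))
        (out / "fits.json").write_text(
            json.dumps(
                [
                    {
                        "subject": f.subject,
                        "alpha_hat": f.alpha_hat,
                        "beta_hat": None if not f.beta_defined else f.beta_hat,
                        "n_trials_used": f.n_trials_used,
                    }
                    for f in fits
                ],
                indent=1,
                sort_keys=True,
            )
            + "\n"
        )
        summary["recovered_params"] = [
            {
                "subject": f.subject,
                "alpha_hat": f.alpha_hat,
                "beta_hat": None if not f.beta_defined else f.beta_hat,
            }
            for f in fits
        ]
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("fit", exc) from exc

    # --- compare ----------------------------------------------------------
    try:
        _stage("compare")
        model_names = list(config.fitting.models)
        rows = {}
        for trials in tables:
            pre = preprocess_trials(trials, drop=False)
            rows[str(trials["subject"].iloc[0])] = [
                crossval_score(pre, m, alpha_grid) for m in model_names
            ]
        scores = pd.DataFrame.from_dict(rows, orient="index", columns=model_names)
        scores.index.name = "subject"
        scores.to_csv(out / "scores.tsv", sep="\t", na_rep="NA", lineterminator="\n")
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("compare", exc) from exc

    # --- bms --------------------------------------------------------------
    try:
        _stage("bms")
        ev = scores_to_log_evidence(scores)
        bms_res = protected_exceedance(
            ev,
            prior_alpha=config.bms.prior_alpha,
            n_samples=config.bms.n_samples,
            seed=seeds[2],
        )
        (out / "bms.json").write_text(json.dumps(bms_res.to_dict(), indent=1, sort_keys=True) + "\n")
        summary["bms"] = {
            "model_names": list(bms_res.model_names),
            "pxp": bms_res.pxp.tolist(),
            "bor": bms_res.bor,
            "best_model": bms_res.model_names[int(np.argmax(bms_res.pxp))],
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("bms", exc) from exc

    if not config.volumes.enabled:
        summary_path = out / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
        return summary

    # --- mvpa -------------------------------------------------------------
    try:
        _stage("mvpa")
        vc = config.volumes
        shape = tuple(vc.shape)
        center = tuple(s // 2 for s in shape)
        mask = sphere_mask(shape, center, vc.mask_radius)
        roi_center = tuple(c + o for c, o in zip(center, vc.roi_offset))
        roi = sphere_mask(shape, roi_center, vc.roi_radius) & mask
        geometry = VolumeGeometry(shape=shape, mask=mask)
        index = build_searchlights(mask, config.mvpa.radius)
        vol_seeds = spawn_seeds(seeds[3], config.n_subjects)

        maps, vol_data, var_data, fold_data = [], [], [], []
        for i, (trials, params) in enumerate(zip(tables, cohort_params)):
            vars_df = compute_model_variables(trials, params.alpha, params.beta)
            spec = EncodingSpec(
                rois=(ROIEncoding(roi=roi, variable=vc.variable, snr=vc.snr),)
            )
            vols = simulate_volumes(trials, vars_df, spec, geometry, vol_seeds[i])
            folds = _fold_labels_from_runs(trials["run"].to_numpy())
            emap = whole_brain_encoding(
                vols,
                vars_df[vc.variable].to_numpy(),
                index,
                folds,
                ridge_penalty=config.mvpa.ridge_penalty,
                variable_name=vc.variable,
                subject=str(trials["subject"].iloc[0]),
            )
            maps.append(emap)
            vol_data.append(vols)
            var_data.append(vars_df)
            fold_data.append(folds)
            if vc.save_nifti:
                write_volumes(
                    vols, geometry.affine, str(trials["subject"].iloc[0]), out / "volumes"
                )
        write_mask(mask, geometry.affine, out / "mask.nii.gz")
        cluster_res = group_cluster_inference(
            maps,
            voxel_p=config.mvpa.voxel_p,
            fwe_alpha=config.mvpa.fwe_alpha,
            n_perm=config.mvpa.n_perm,
            seed=seeds[4],
        )
        cluster_res.clusters.to_csv(out / "clusters.tsv", sep="\t", index=False, lineterminator="\n")
        summary["mvpa"] = {
            "variable": vc.variable,
            "n_clusters_significant": int(cluster_res.clusters["significant"].sum()),
            "largest_cluster": int(cluster_res.clusters["size"].max()) if len(cluster_res.clusters) else 0,
            "cluster_size_threshold": cluster_res.cluster_size_threshold,
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("mvpa", exc) from exc

    # --- permute ----------------------------------------------------------
    try:
        _stage("permute")
        roi_lin = np.flatnonzero(roi[tuple(index.centers.T)])
        betas = np.array(
            [f.beta_hat if f.beta_defined else 0.0 for f in fits]
        )
        perm = pseudo_beta_permutation(
            vol_data,
            [v["P_cue"].to_numpy() for v in var_data],
            [v["P_int"].to_numpy() for v in var_data],
            betas,
            roi_lin,
            index,
            fold_data,
            n_perm=config.mvpa.pseudo_n_perm,
            statistic=config.mvpa.statistic,
            seed=seeds[5],
            ridge_penalty=config.mvpa.ridge_penalty,
        )
        perm_out = {
            "statistic": perm.statistic,
            "observed": perm.observed,
            "p_value": perm.p_value,
            "n_perm": int(perm.null_stats.size),
        }
        if perm.null_stats.size >= 100:
            r, p = distance_decay(betas, perm.beta_tilde, perm.null_strengths)
            perm_out["distance_decay_r"] = r
            perm_out["distance_decay_p"] = p
        (out / "permutation.json").write_text(json.dumps(perm_out, indent=1, sort_keys=True) + "\n")
        summary["permutation"] = perm_out
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("permute", exc) from exc

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    log.info("pipeline done: %s", summary_path)
    return summary
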