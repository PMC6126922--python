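"""File formats: trial tables (TSV), volumes (NIfTI-1 + JSON sidecar),
and YAML/JSON configuration."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "read_volumes",
    "write_volumes",
    "read_mask",
    "write_mask",
    "load_config_file",
]

TRIAL_COLUMNS = ["subject", "run", "trial", "task", "precue", "rt", "correct"]


class SchemaError(ValueError):
    """A file does not match the expected layout."""


def write_trials(trials: pd.DataFrame, path) -> Path:
    """Write a trial table as TSV (tab separator, ``NA`` missing, Unix EOL)."""
    path = Path(path)
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table lacks columns: {missing}")
    extra = [c for c in trials.columns if c not in TRIAL_COLUMNS]
    trials[TRIAL_COLUMNS + extra].to_csv(
        path, sep="\t", index=False, na_rep="NA", lineterminator="\n", encoding="utf-8"
    )
    return path


def read_trials(path) -> pd.DataFrame:
    """Read a TSV trial table, validating columns and basic invariants."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False, encoding="utf-8")
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    if len(df):
        task = df["task"].to_numpy(dtype=float)
        if not np.all(np.isin(task[np.isfinite(task)], (0.0, 1.0))):
            raise SchemaError(f"{path}: column 'task' must be coded 0/1")
        rt = df["rt"].to_numpy(dtype=float)
        if np.any(rt[np.isfinite(rt)] <= 0):
            raise SchemaError(f"{path}: column 'rt' must be positive where present")
        for sub, g in df.groupby("subject", sort=False):
            if not np.all(np.diff(g["trial"].to_numpy()) > 0):
                raise SchemaError(f"{path}: column 'trial' must increase chronologically")
    df["subject"] = df["subject"].astype(str)
    return df


def write_volumes(
    volumes: np.ndarray,
    affine: np.ndarray,
    subject: str,
    out_dir,
    variable_names: list[str] | None = None,
) -> tuple[Path, Path]:
    """Write per-trial volumes as one 4D NIfTI plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nii_path = out_dir / f"{subject}_trials.nii.gz"
    nib.save(nib.Nifti1Image(np.asarray(volumes, dtype=np.float32), affine), nii_path)
    sidecar = {
        "subject": subject,
        "n_trials": int(volumes.shape[3]),
        "variable_names": variable_names or [],
    }
    json_path = out_dir / f"{subject}_trials.json"
    json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n")
    return nii_path, json_path


def read_volumes(nii_path) -> tuple[np.ndarray, dict]:
    """Read a 4D NIfTI volume file and its sidecar; validate trial count."""
    nii_path = Path(nii_path)
    img = nib.load(nii_path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise SchemaError(f"{nii_path}: expected a 4D image, got {data.ndim}D")
    sidecar_path = Path(str(nii_path).removesuffix(".nii.gz").removesuffix(".nii") + ".json")
    sidecar = json.loads(sidecar_path.read_text())
    if sidecar.get("n_trials") != data.shape[3]:
        raise SchemaError(
            f"{nii_path}: sidecar reports {sidecar.get('n_trials')} trials, "
            f"image has {data.shape[3]}"
        )
    return data, sidecar


def write_mask(mask: np.ndarray, affine: np.ndarray, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), path)
    return path


def read_mask(path) -> np.ndarray:
    img = nib.load(path)
    return np.asarray(img.dataobj) > 0


def load_config_file(path) -> dict:
    """Load a YAML or JSON configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
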