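"""Reading and writing the pipeline's artifacts.

Volumes (BOLD runs, masks, pattern stacks, maps) are NIfTI via nibabel;
events and result tables are BIDS-style TSV with missing values encoded as
"n/a"; configuration and ground truth are YAML/JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .design import (
    AuxEvent,
    Condition,
    ExperimentDesign,
    TimingConfig,
    TrialEvent,
)
from .lss import TrialPatternSet
from .simulate import BoldDataset, GroundTruth, VolumeGeometry

__all__ = [
    "write_events_tsv",
    "read_events_tsv",
    "design_from_events",
    "save_bold",
    "load_bold",
    "save_mask",
    "load_mask",
    "save_pattern_set",
    "load_pattern_set",
    "write_table",
    "read_table",
    "save_ground_truth",
    "load_ground_truth",
    "save_config",
    "load_config",
]


class IoError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="n/a")
    return path

def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IoError(f"no such table: {path}")
    df = pd.read_csv(path, sep="\t", na_values=["n/a"], keep_default_na=False)
    for col in df.columns:
        if df[col].dtype == object and set(df[col].dropna()) <= {"True", "False"}:
            df[col] = df[col].map({"True": True, "False": False})
    return df


def write_events_tsv(design: ExperimentDesign, path: str | Path, run: int | None = None) -> Path:
    return write_table(design.events_table(run), path)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    return read_table(path)


def design_from_events(
    events: pd.DataFrame, subject_id: str = "sub-01", seed: int = 0
) -> ExperimentDesign:
    """Rebuild an analyzable design from a BIDS-style events table (the
    stimulus-response map is not recoverable and is left empty)."""
    trials: list[TrialEvent] = []
    aux: list[AuxEvent] = []
    for _, row in events.iterrows():
        if row["trial_type"] == "trial":
            trials.append(
                TrialEvent(
                    run=int(row["run"]),
                    block=int(row["block"]),
                    condition=Condition(row["condition"]),
                    stage=row["stage"],
                    stimulus=int(row["stimulus"]),
                    repetition=int(row["repetition"]),
                    onset=float(row["onset"]),
                    duration=float(row["duration"]),
                    response=None if pd.isna(row["response"]) else int(row["response"]),
                    correct=None if pd.isna(row["correct"]) else bool(row["correct"]),
                    rt=None if pd.isna(row["rt"]) else float(row["rt"]),
                    recoded_repetition=None
                    if pd.isna(row["recoded_repetition"])
                    else int(row["recoded_repetition"]),
                )
            )
        else:
            aux.append(
                AuxEvent(
                    kind=row["trial_type"],
                    onset=float(row["onset"]),
                    duration=float(row["duration"]),
                    run=int(row["run"]),
                    block=int(row["block"]),
                    condition=Condition(row["condition"]),
                )
            )
    design = ExperimentDesign(
        subject_id=subject_id,
        trials=trials,
        aux_events=aux,
        stimulus_response_map={},
        seed=seed,
        timing=TimingConfig(),
    )
    design.validate()
    return design


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def save_bold(bold: BoldDataset, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(bold.data, bold.geometry.affine)
    img.header.set_zooms((*bold.geometry.voxel_size, bold.tr))
    img.to_filename(str(path))
    return path


def load_bold(
    path: str | Path,
    tr: float | None = None,
    n_discard: int = 3,
    run: int = 1,
    brain_mask: np.ndarray | None = None,
) -> BoldDataset:
    path = Path(path)
    if not path.exists():
        raise IoError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    mask = (
        np.ones(data.shape[:3], dtype=bool) if brain_mask is None else brain_mask
    )
    geometry = VolumeGeometry(data.shape[:3], img.affine, mask)
    return BoldDataset(data=data, tr=tr, geometry=geometry, n_discard=n_discard, run=run)


def save_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.Nifti1Image(mask.astype(np.uint8), affine).to_filename(str(path))
    return path


def load_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(Path(path)))
    return np.asarray(img.dataobj) > 0, img.affine


# ---------------------------------------------------------------------------
# Trial pattern sets
# ---------------------------------------------------------------------------

def save_pattern_set(tps: TrialPatternSet, prefix: str | Path) -> dict[str, Path]:
    """Serialize as a 4D NIfTI stack (trial axis last), a mask volume, and a
    TSV index; readable back losslessly."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    affine = tps.geometry.affine if tps.geometry is not None else np.eye(4)
    vol = np.full(tps.mask.shape + (tps.n_trials,), np.nan)
    vol[tps.mask] = tps.data.T
    paths = {
        "data": Path(f"{prefix}_patterns.nii.gz"),
        "mask": Path(f"{prefix}_mask.nii.gz"),
        "index": Path(f"{prefix}_index.tsv"),
    }
    nib.Nifti1Image(vol, affine).to_filename(str(paths["data"]))
    save_mask(tps.mask, affine, paths["mask"])
    write_table(tps.index, paths["index"])
    return paths


def load_pattern_set(prefix: str | Path, stat: str = "t") -> TrialPatternSet:
    prefix = Path(prefix)
    data_path = Path(f"{prefix}_patterns.nii.gz")
    if not data_path.exists():
        raise IoError(f"no such pattern stack: {data_path}")
    img = nib.load(str(data_path))
    vol = np.asarray(img.dataobj, dtype=float)
    mask, affine = load_mask(f"{prefix}_mask.nii.gz")
    index = read_table(f"{prefix}_index.tsv")
    geometry = VolumeGeometry(vol.shape[:3], affine, mask)
    return TrialPatternSet(
        data=vol[mask].T.copy(), index=index, mask=mask, geometry=geometry, stat=stat
    )


# ---------------------------------------------------------------------------
# Ground truth / config
# ---------------------------------------------------------------------------

def save_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(
        params=gt.params,
        trial_amplitudes={k: v.tolist() for k, v in gt.trial_amplitudes.items()},
        region_voxels={k: v.tolist() for k, v in gt.region_voxels.items()},
        patterns_learning={
            reg: {str(s): v.tolist() for s, v in pats.items()}
            for reg, pats in gt.patterns_learning.items()
        },
        patterns_implementation={
            reg: {str(s): v.tolist() for s, v in pats.items()}
            for reg, pats in gt.patterns_implementation.items()
        },
    )
    path.write_text(json.dumps(payload))
    return path


def load_ground_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    if not path.exists():
        raise IoError(f"no such ground truth file: {path}")
    payload = json.loads(path.read_text())
    return GroundTruth(
        patterns_learning={
            reg: {int(s): np.array(v) for s, v in pats.items()}
            for reg, pats in payload["patterns_learning"].items()
        },
        patterns_implementation={
            reg: {int(s): np.array(v) for s, v in pats.items()}
            for reg, pats in payload["patterns_implementation"].items()
        },
        trial_amplitudes={
            k: np.array(v) for k, v in payload["trial_amplitudes"].items()
        },
        region_voxels={k: np.array(v) for k, v in payload["region_voxels"].items()},
        params=payload["params"],
    )


def save_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config, sort_keys=False))
    return path


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise IoError(f"no such config: {path}")
    try:
        config = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise IoError(f"cannot parse config {path}: {err}") from err
    if not isinstance(config, dict):
        raise IoError(f"config {path} is not a mapping")
    return config
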