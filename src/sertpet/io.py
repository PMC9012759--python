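"""File formats: TAC TSV, profile/clinical CSV, NIfTI maps, YAML config.

Dialects: UTF-8, '.' decimal, mandatory header row.  TACs are long-format
TSV with columns (region, frame_start_min, frame_duration_min,
value_kBq_mL); profiles are CSV with a ``subject_id`` index column.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .tac import FrameSchedule, TimeActivityCurve

__all__ = [
    "write_tacs",
    "read_tacs",
    "write_profile",
    "read_profile",
    "write_clinical",
    "read_clinical",
    "write_map",
    "read_map",
    "load_yaml",
    "dump_yaml",
]

TAC_COLUMNS = ["region", "frame_start_min", "frame_duration_min", "value_kBq_mL"]


def write_tacs(tacs: dict[str, TimeActivityCurve], path: str | Path) -> None:
    rows = []
    for region, tac in tacs.items():
        for s, d, v in zip(
            tac.schedule.frame_starts, tac.schedule.frame_durations, tac.values
        ):
            rows.append((region, s, d, v))
    pd.DataFrame(rows, columns=TAC_COLUMNS).to_csv(path, sep="\t", index=False)


def read_tacs(path: str | Path) -> dict[str, TimeActivityCurve]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TAC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"TAC file {path} lacks required columns: {missing}")
    out = {}
    for region, sub in df.groupby("region", sort=False):
        sub = sub.sort_values("frame_start_min")
        sched = FrameSchedule(
            sub["frame_start_min"].to_numpy(float),
            sub["frame_duration_min"].to_numpy(float),
        )
        out[str(region)] = TimeActivityCurve(
            sched, sub["value_kBq_mL"].to_numpy(float), str(region)
        )
    return out


def write_profile(profile: pd.DataFrame, path: str | Path) -> None:
    profile.to_csv(path, index_label="subject_id")


def read_profile(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"profile file {path} lacks a 'subject_id' column")
    df = df.set_index("subject_id")
    if df.isna().any().any():
        raise ValueError(f"profile file {path} contains missing cells")
    return df


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, index_label="subject_id")


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"clinical file {path} lacks a 'subject_id' column")
    df = df.set_index("subject_id")
    for col in ("psychiatric_lifetime", "genotype_LaLa"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_map(
    data: np.ndarray, path: str | Path, *, affine: np.ndarray | None = None,
    voxel_size_mm: float = 2.0,
) -> None:
    if affine is None:
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def read_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping at top level")
    return data


def dump_yaml(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
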