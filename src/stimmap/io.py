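"""Readers and writers: NIfTI volumes, cohort tables, lead coordinates.

Volumes are written as NIfTI-1 with a diagonal RAS+ affine in template mm
(float32 for maps, uint8 for masks); statistics always run in double
precision. The cohort round-trips through three plain files: a CSV table
(scores, settings), a JSON file of lead contact coordinates, and one 4D
NIfTI mask stack per hemisphere.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import Cohort, Subject
from .grid import VoxelGrid
from .vta import LeadGeometry, StimSetting, VTAMask

__all__ = [
    "read_volume",
    "write_volume",
    "read_cohort_table",
    "write_cohort_table",
    "save_cohort",
    "load_cohort",
]

_SUPPORTED_DTYPES = ("uint8", "int16", "int32", "float32", "float64")


def write_volume(grid: VoxelGrid, values: np.ndarray, path) -> Path:
    """Write a volume on ``grid`` as NIfTI-1; masks as uint8, maps as float32."""
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise ValueError(f"volume shape {values.shape} does not match grid {grid.shape}")
    if values.dtype == bool or values.dtype == np.uint8:
        data = values.astype(np.uint8)
    elif np.issubdtype(values.dtype, np.integer):
        data = values.astype(np.int32)
    else:
        data = values.astype(np.float32)
    img = nib.Nifti1Image(data, grid.affine)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, path)
    return path


def read_volume(path) -> tuple[VoxelGrid, np.ndarray]:
    """Read a NIfTI volume; returns its grid and data array.

    The affine must be axis-aligned RAS+ (obliquity beyond tolerance is
    rejected with guidance); integer masks round-trip bit-exactly, float
    maps at float32 precision.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.dtype.name not in _SUPPORTED_DTYPES:
        raise TypeError(
            f"{path}: unsupported volume datatype {data.dtype.name}; "
            f"expected one of {_SUPPORTED_DTYPES}"
        )
    grid = VoxelGrid.from_affine(img.shape[:3], img.affine)
    return grid, data


# ----------------------------------------------------------------------
# cohort tables

REQUIRED_COLUMNS = ("subject_id", "state", "score_pre", "score_post")
SIDES = ("left", "right")


def write_cohort_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.17g")  # %.17g round-trips float64
    return path


def read_cohort_table(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Required columns: subject_id, state, score_pre, score_post. Rows with
    missing required fields or non-positive baseline scores are rejected
    with their ids listed; unknown columns pass through untouched.
    """
    table = pd.read_csv(path, float_precision="round_trip")
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    bad = table[list(REQUIRED_COLUMNS)].isna().any(axis=1) | (table["score_pre"] <= 0)
    if bad.any():
        offenders = table.loc[bad, "subject_id"].tolist()
        raise ValueError(
            f"{path}: invalid rows (missing required fields or score_pre <= 0): {offenders}"
        )
    if "pct_improvement" not in table.columns:
        table["pct_improvement"] = 100.0 * (table["score_pre"] - table["score_post"]) / table["score_pre"]
    return table


# ----------------------------------------------------------------------
# full-cohort persistence (table + lead coordinates + mask stacks)


def save_cohort(cohort: Cohort, directory) -> Path:
    """Write a cohort as cohort.csv, leads.json and masks_<side>.nii.gz."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_cohort_table(cohort.to_table(), directory / "cohort.csv")
    leads = {
        s.subject_id: {
            side: {
                "contact_centres": lead.contact_centres.tolist(),
                "pitch": lead.pitch,
                "model_name": lead.model_name,
            }
            for side, lead in s.lead_geometry.items()
        }
        for s in cohort.subjects
    }
    (directory / "leads.json").write_text(json.dumps(leads, indent=1))
    for side in SIDES:
        stack = np.stack([s.vta_masks[side].to_array() for s in cohort.subjects], axis=-1)
        img = nib.Nifti1Image(stack.astype(np.uint8), cohort.grid.affine)
        nib.save(img, directory / f"masks_{side}.nii.gz")
    return directory


def load_cohort(directory) -> Cohort:
    """Rebuild a cohort written by :func:`save_cohort`."""
    directory = Path(directory)
    table = read_cohort_table(directory / "cohort.csv")
    leads = json.loads((directory / "leads.json").read_text())
    stacks = {}
    grid = None
    for side in SIDES:
        img = nib.load(str(directory / f"masks_{side}.nii.gz"))
        grid = VoxelGrid.from_affine(img.shape[:3], img.affine)
        stacks[side] = np.asanyarray(img.dataobj)
    subjects = []
    for row_idx, row in table.iterrows():
        sid = str(row["subject_id"])
        geometry, settings, masks = {}, {}, {}
        for side in SIDES:
            spec = leads[sid][side]
            geometry[side] = LeadGeometry(
                contact_centres=np.asarray(spec["contact_centres"], dtype=float),
                pitch=float(spec["pitch"]),
                side=side,
                model_name=spec.get("model_name", "generic-quadripolar"),
            )
            settings[side] = StimSetting(
                contact_index=int(row[f"contact_{side}"]),
                amplitude=float(row[f"amplitude_{side}"]),
                pulse_width_us=float(row[f"pulse_width_us_{side}"]),
                frequency_hz=float(row[f"frequency_hz_{side}"]),
                amplitude_unit=str(row.get(f"amplitude_unit_{side}", "mA")),
            )
            masks[side] = VTAMask(grid, np.argwhere(stacks[side][..., row_idx] > 0))
        subjects.append(
            Subject(
                subject_id=sid,
                score_pre=float(row["score_pre"]),
                score_post=float(row["score_post"]),
                centre=str(row.get("centre", "unknown")),
                scale=str(row.get("scale", "MDS-UPDRS-III")),
                state=str(row.get("state", "MED-OFF")),
                lead_geometry=geometry,
                settings=settings,
                vta_masks=masks,
            )
        )
    return Cohort(grid=grid, subjects=subjects)
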