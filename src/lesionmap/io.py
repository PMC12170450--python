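"""NIfTI mask and behavior-table I/O.

World coordinates follow the NIfTI affine convention (RAS mm); voxel indices
are 0-based. Masks are binarized at 0.5 on read, with nonbinary voxels
counted and logged.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .mask import LesionMask

__all__ = [
    "read_mask",
    "write_mask",
    "read_behavior",
    "write_behavior",
    "read_atlas",
    "BEHAVIOR_SCHEMA_VERSION",
]

log = logging.getLogger(__name__)

BEHAVIOR_SCHEMA_VERSION = "lesionmap-behavior-v1"

REQUIRED_BEHAVIOR_COLUMNS = (
    "subject_id",
    "instrument",
    "aos",
    "days_post_surgery",
    "lesion_cm3",
)


def read_mask(path: str | Path, reference: LesionMask | None = None) -> LesionMask:
    """Read a 3-D NIfTI volume as a binary lesion mask.

    Values are binarized at 0.5; the count of nonbinary voxels is logged.
    If ``reference`` is given, shape and affine must match it.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    data = np.asarray(data, dtype=float)
    nonbinary = int(((data != 0) & (data != 1)).sum())
    if nonbinary:
        log.info("%s: %d nonbinary voxels binarized at 0.5", path, nonbinary)
    mask = LesionMask(data > 0.5, img.affine)
    if reference is not None and not mask.same_grid(reference):
        raise ValueError(
            f"{path}: grid mismatch with cohort reference "
            f"(shape {mask.shape} vs {reference.shape})"
        )
    return mask


def write_mask(mask: LesionMask, path: str | Path) -> Path:
    """Write a lesion mask as uint8 NIfTI; write-then-read is identity."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))
    return path


def write_volume(
    data: np.ndarray, affine: np.ndarray, path: str | Path
) -> Path:
    """Write a float volume (e.g. a t-map with NaN sentinels) as NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))
    return path


def read_atlas(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an integer-labeled atlas volume; returns (labels volume, affine)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: atlas must be 3-D, got shape {data.shape}")
    return np.rint(data).astype(int), img.affine


def write_behavior(behavior: pd.DataFrame, path: str | Path) -> Path:
    """Write the behavior table with a schema-version header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {BEHAVIOR_SCHEMA_VERSION}\n")
        behavior.to_csv(fh, index=False)
    return path


def read_behavior(path: str | Path) -> pd.DataFrame:
    """Read a behavior CSV, checking the schema version and required columns.

    Unknown columns are preserved; missing required columns are fatal.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#"):
        version = first.lstrip("# ").strip()
        if version != BEHAVIOR_SCHEMA_VERSION:
            raise ValueError(
                f"{path}: unsupported behavior schema {version!r}; "
                f"expected {BEHAVIOR_SCHEMA_VERSION!r}"
            )
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df
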