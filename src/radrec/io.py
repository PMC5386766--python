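"""Readers and writers for volumes, masks, cohort tables and configuration.

Volumes and masks travel as NIfTI-1; cohort and feature tables as
comma-separated UTF-8 with a header row (booleans as 0/1); run
configuration as YAML.  Voxel indexing is plain 0-based array index
space — no world-coordinate transform is applied, since all synthetic
inputs are generated on a single shared grid.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .types import (
    CohortTable,
    ROIMask,
    ValidationError,
    Volume3D,
    check_same_grid,
)

log = logging.getLogger("radrec")


def configure_logging(verbose: bool = False) -> None:
    level = logging.DEBUG if verbose else logging.INFO
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")


def read_volume(path, role: str = "generic") -> Volume3D:
    """Read a 3-D NIfTI volume.

    Raises a dimensionality error if a 4-D file is passed where a 3-D
    volume is expected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]
    ) else data
    if data.ndim != 3:
        raise ValidationError(
            f"{path} is {data.ndim}-D; expected a 3-D volume"
        )
    return Volume3D(values=np.asarray(data, dtype=float), role=role)


def write_volume(volume: Volume3D, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float64), affine=np.eye(4))
    nib.save(img, str(path))


def read_mask(path, role: str = "lesion", grid_shape: Optional[tuple] = None) -> ROIMask:
    """Read a binary ROI mask; any nonzero voxel counts as inside."""
    vol = read_volume(path, role="mask")
    if grid_shape is not None:
        check_same_grid(vol.grid_shape, grid_shape, what=f"{role} mask file")
    return ROIMask(voxels=vol.values != 0, role=role)


def write_mask(mask: ROIMask, path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine=np.eye(4))
    nib.save(img, str(path))


def read_series(path, tr_seconds: float, te_seconds: float, n_baseline: int = 4):
    """Read a 4-D dynamic series; timing metadata is supplied by the caller
    (NIfTI headers do not reliably carry TR/TE)."""
    from .types import DynamicSeries

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = np.asanyarray(nib.load(str(path)).dataobj)
    if data.ndim != 4:
        raise ValidationError(f"{path} is {data.ndim}-D; expected a 4-D series")
    return DynamicSeries(
        signal=np.asarray(data, dtype=float),
        tr_seconds=tr_seconds,
        te_seconds=te_seconds,
        n_baseline=n_baseline,
    )


def write_series(series, path) -> None:
    img = nib.Nifti1Image(np.asarray(series.signal, dtype=np.float64), affine=np.eye(4))
    nib.save(img, str(path))


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV (patient_id, group, grade, survival_days, event,
    optional feature columns)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return CohortTable.from_frame(pd.read_csv(path))


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.to_frame().to_csv(path, index=False)


def write_features(cohort: CohortTable, path) -> None:
    """Write one row per patient with all feature columns at full precision.

    Errors, naming the offending patients, if any record lacks computed
    features.
    """
    missing = [r.patient_id for r in cohort.records if r.features is None]
    if missing:
        raise ValidationError(f"records lacking computed features: {missing}")
    write_cohort(cohort, path)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
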