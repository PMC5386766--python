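"""Domain types shared by every stage of the pipeline.

The pipeline distinguishes recurrent high-grade glioma from radionecrosis
using two imaging statistics computed inside the contrast-enhancing lesion:
percentile points of the normalized cerebral blood volume (nCBV) histogram
from DSC perfusion MRI, and the proportion of dark signal on a
susceptibility-weighted image (proSWMRI).  The types below carry the raw
volumes, masks, per-patient features and cohort bookkeeping between stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

GROUPS = ("recurrence", "radionecrosis")
GRADES = ("III", "IV")
MASK_ROLES = ("lesion", "nawm", "ventricle", "nonenhancing_reference")
FEATURE_COLUMNS = ("mean_ncbv", "ncbv70", "ncbv90", "ncbv95", "ncbv99", "pro_swmri")

#: positive class for every classifier in the package
POSITIVE_CLASS = "recurrence"


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class DynamicSeries:
    """A 4-D dynamic susceptibility contrast signal series.

    Parameters
    ----------
    signal : ndarray, shape (x, y, z, t)
        Raw MR magnitude signal, arbitrary units, strictly positive inside
        any brain mask that will be applied.
    tr_seconds : float
        Repetition time; also the temporal sampling interval.
    te_seconds : float
        Echo time used for the ΔR2* conversion.
    n_baseline : int
        Number of pre-bolus time points (the bolus is injected after
        four to five acquisitions in the emulated protocol).
    """

    signal: np.ndarray
    tr_seconds: float
    te_seconds: float
    n_baseline: int = 4

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValidationError(
                f"dynamic series must be 4-D (x, y, z, t); got {self.signal.ndim}-D"
            )
        if self.tr_seconds <= 0 or self.te_seconds <= 0:
            raise ValidationError("tr_seconds and te_seconds must be > 0")
        if self.n_baseline < 2:
            raise ValidationError("n_baseline must be >= 2")
        if self.signal.shape[-1] < self.n_baseline + 10:
            raise ValidationError(
                "time axis must contain at least n_baseline + 10 points; "
                f"got {self.signal.shape[-1]} with n_baseline={self.n_baseline}"
            )

    @property
    def grid_shape(self) -> tuple:
        return self.signal.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.signal.shape[-1]

    @property
    def times(self) -> np.ndarray:
        """Acquisition times in seconds (0, TR, 2 TR, ...)."""
        return np.arange(self.n_timepoints) * self.tr_seconds


@dataclass
class Volume3D:
    """A 3-D scalar volume with a role tag (nCBV map, SWI magnitude, ...)."""

    values: np.ndarray
    role: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError(f"volume must be 3-D; got {self.values.ndim}-D")

    @property
    def grid_shape(self) -> tuple:
        return self.values.shape


@dataclass
class ROIMask:
    """A boolean region-of-interest mask on the same grid as its volume."""

    voxels: np.ndarray
    role: str = "lesion"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels) != 0
        if self.voxels.ndim != 3:
            raise ValidationError(f"mask must be 3-D; got {self.voxels.ndim}-D")
        if self.role not in MASK_ROLES:
            raise ValidationError(
                f"unknown mask role {self.role!r}; expected one of {MASK_ROLES}"
            )
        if not self.voxels.any():
            raise ValidationError(f"mask with role {self.role!r} is empty")

    @property
    def grid_shape(self) -> tuple:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def extract(self, volume: Volume3D | np.ndarray) -> np.ndarray:
        """Return the masked voxel values as a flat vector."""
        values = volume.values if isinstance(volume, Volume3D) else np.asarray(volume)
        check_same_grid(values.shape[:3], self.grid_shape, what=f"{self.role} mask")
        return values[self.voxels]


def check_same_grid(shape_a: tuple, shape_b: tuple, what: str = "mask") -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise ValidationError(
            f"grid shape mismatch: volume {tuple(shape_a)} vs {what} {tuple(shape_b)}"
        )


def check_disjoint(*masks: ROIMask) -> None:
    """Lesion / NAWM / ventricle ROIs must not overlap."""
    total = np.zeros(masks[0].grid_shape, dtype=int)
    for m in masks:
        check_same_grid(m.grid_shape, masks[0].grid_shape, what=f"{m.role} mask")
        total += m.voxels.astype(int)
    if (total > 1).any():
        raise ValidationError("ROI masks overlap; lesion/nawm/ventricle must be disjoint")


@dataclass
class LesionFeatures:
    """Per-patient feature vector: mean nCBV, four nCBV percentile points
    of the cumulative lesion histogram, and proSWMRI (%)."""

    mean_ncbv: float
    ncbv70: float
    ncbv90: float
    ncbv95: float
    ncbv99: float
    pro_swmri: float

    def __post_init__(self) -> None:
        pts = (self.ncbv70, self.ncbv90, self.ncbv95, self.ncbv99)
        if not all(a <= b + 1e-12 for a, b in zip(pts, pts[1:])):
            raise ValidationError(
                f"percentile points must be nondecreasing; got {pts}"
            )
        if not (0.0 <= self.pro_swmri <= 100.0):
            raise ValidationError(f"pro_swmri must lie in [0, 100]; got {self.pro_swmri}")

    def as_dict(self) -> dict:
        return {c: float(getattr(self, c)) for c in FEATURE_COLUMNS}


@dataclass
class PatientRecord:
    patient_id: str
    group: str
    grade: str = "IV"
    survival_days: int = 0
    event: bool = False
    features: Optional[LesionFeatures] = None
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r} for patient {self.patient_id}; "
                f"expected one of {GROUPS}"
            )
        if self.grade not in GRADES:
            raise ValidationError(
                f"unknown grade {self.grade!r} for patient {self.patient_id}"
            )
        if self.survival_days < 0:
            raise ValidationError(
                f"survival_days must be >= 0 for patient {self.patient_id}"
            )


@dataclass
class CohortTable:
    """Ordered collection of patient records with unique ids."""

    records: Sequence[PatientRecord]

    def __post_init__(self) -> None:
        self.records = list(self.records)
        ids = [r.patient_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate patient_id(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, group: str) -> "CohortTable":
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}")
        return CohortTable([r for r in self.records if r.group == group])

    def labels(self) -> np.ndarray:
        return np.array([r.group for r in self.records])

    def feature_matrix(self, columns: Sequence[str]) -> np.ndarray:
        """Stack the named feature columns, erroring on missing features."""
        missing = [r.patient_id for r in self.records if r.features is None]
        if missing:
            raise ValidationError(f"records lacking computed features: {missing}")
        return np.array(
            [[getattr(r.features, c) for c in columns] for r in self.records]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "patient_id": r.patient_id,
                "group": r.group,
                "grade": r.grade,
                "survival_days": int(r.survival_days),
                "event": int(r.event),
            }
            if r.features is not None:
                row.update(r.features.as_dict())
            for k, v in r.covariates.items():
                row[k] = v
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CohortTable":
        required = {"patient_id", "group", "grade", "survival_days", "event"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
        has_features = set(FEATURE_COLUMNS) <= set(frame.columns)
        extra = [
            c
            for c in frame.columns
            if c not in required and c not in FEATURE_COLUMNS
        ]
        records = []
        for _, row in frame.iterrows():
            features = None
            if has_features and not any(pd.isna(row[c]) for c in FEATURE_COLUMNS):
                features = LesionFeatures(**{c: float(row[c]) for c in FEATURE_COLUMNS})
            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    group=str(row["group"]),
                    grade=str(row["grade"]),
                    survival_days=int(row["survival_days"]),
                    event=bool(int(row["event"])),
                    features=features,
                    covariates={k: row[k] for k in extra if not pd.isna(row[k])},
                )
            )
        return cls(records)
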