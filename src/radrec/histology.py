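"""Histopathologic hemorrhagic-foci quantification.

Hemorrhagic foci within resected lesion tissue are size-classed by longest
diameter (≤ 5 mm vs > 5 mm).  Per patient, the percentage of foci in each
class is recorded; groups are summarised by the unweighted mean of those
per-patient percentages (not the pooled-count proportion, which differs)
and compared with the exact Mann–Whitney U test.  A fixture table with the
published per-patient values ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import group_compare
from .types import GROUPS, ValidationError

SIZE_CLASSES = ("small", "large")  # ≤ 5 mm, > 5 mm


@dataclass
class FociRecord:
    patient_id: str
    group: str
    pct_small: float
    pct_large: float
    n_small: Optional[int] = None
    n_large: Optional[int] = None
    pro_swmri: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if abs(self.pct_small + self.pct_large - 100.0) > 2.0:
            raise ValidationError(
                f"size-class percentages must sum to ~100; got "
                f"{self.pct_small} + {self.pct_large} for {self.patient_id}"
            )
        for n in (self.n_small, self.n_large):
            if n is not None and n < 0:
                raise ValidationError("foci counts must be >= 0")


def proportions_from_counts(n_small: int, n_large: int) -> tuple[float, float]:
    """(pct ≤5 mm, pct >5 mm) from raw foci counts."""
    total = n_small + n_large
    if total < 1:
        raise ValidationError("at least one focus required")
    return 100.0 * n_small / total, 100.0 * n_large / total


def group_average_proportion(
    records: Sequence[FociRecord], group: str, size_class: str
) -> float:
    """Unweighted mean of per-patient percentages for one group and size
    class (round for display; the unrounded value is returned)."""
    if size_class not in SIZE_CLASSES:
        raise ValidationError(f"unknown size class {size_class!r}")
    values = [
        r.pct_small if size_class == "small" else r.pct_large
        for r in records
        if r.group == group
    ]
    if not values:
        raise ValidationError(f"no records in group {group!r}")
    return float(np.mean(values))


def compare_foci_groups(records: Sequence[FociRecord], size_class: str = "small") -> float:
    """Two-sided Mann–Whitney p comparing per-patient percentages between
    recurrence and radionecrosis."""
    rec = [
        (r.pct_small if size_class == "small" else r.pct_large)
        for r in records
        if r.group == "recurrence"
    ]
    nec = [
        (r.pct_small if size_class == "small" else r.pct_large)
        for r in records
        if r.group == "radionecrosis"
    ]
    if not rec or not nec:
        raise ValidationError("both groups must be nonempty")
    return group_compare(rec, nec, method="mann_whitney")[1]


def read_foci_table(path=None) -> list[FociRecord]:
    """Read a foci CSV (patient_id, group, pct_small, pct_large, n_small,
    n_large, pro_swmri); defaults to the packaged published-values fixture."""
    if path is None:
        with resources.as_file(
            resources.files("radrec").joinpath("data/hemorrhagic_foci.csv")
        ) as p:
            frame = pd.read_csv(p)
    else:
        frame = pd.read_csv(path)
    records = []
    for _, row in frame.iterrows():
        records.append(
            FociRecord(
                patient_id=str(row["patient_id"]),
                group=str(row["group"]),
                pct_small=float(row["pct_small"]),
                pct_large=float(row["pct_large"]),
                n_small=None if pd.isna(row.get("n_small")) else int(row["n_small"]),
                n_large=None if pd.isna(row.get("n_large")) else int(row["n_large"]),
                pro_swmri=None
                if pd.isna(row.get("pro_swmri"))
                else float(row["pro_swmri"]),
            )
        )
    return records
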