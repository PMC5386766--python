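"""Susceptibility-weighted hypointensity quantification.

Blood products (hemorrhage) appear dark on susceptibility-weighted
magnitude images.  proSWMRI summarises that per lesion as the percentage
of enhancing-lesion voxels whose signal falls strictly below a reference
intensity, the pooled median over a ventricular ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ROIMask, ValidationError, Volume3D


@dataclass
class ReferenceSI:
    """Reference signal intensity: median over the ventricle mask."""

    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValidationError("reference SI must be finite")


def reference_signal(swmri: Volume3D, ventricle_mask: ROIMask) -> ReferenceSI:
    """Median signal over the ventricle ROI, pooled across all slices.

    Even-count medians use the mean of the two central order statistics.
    """
    values = ventricle_mask.extract(swmri)
    if values.size == 0:
        raise ValidationError("empty ventricle mask")
    return ReferenceSI(value=float(np.median(values)))


def pro_swmri(swmri: Volume3D, lesion_mask: ROIMask, ref: ReferenceSI) -> float:
    """100 × (lesion voxels strictly below the reference SI) / (lesion voxels).

    Voxels exactly equal to the reference count as not-dark.
    """
    values = lesion_mask.extract(swmri)
    if values.size == 0:
        raise ValidationError("empty lesion mask")
    return float(100.0 * np.count_nonzero(values < ref.value) / values.size)
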