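"""Cumulative-histogram analysis of lesion nCBV values and per-patient
feature assembly.

The lesion volume of interest is the union of the enhancing-lesion ROI
across all slices.  Its nCBV distribution is summarised by the mean and by
percentile points of the cumulative histogram (bin width 0.1); the Xth
percentile point is the nCBV value to the left of which X% of lesion
voxels lie.  The 90th point (nCBV90) is the primary discriminator between
recurrence and radionecrosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import LesionFeatures, ROIMask, ValidationError, Volume3D

BIN_WIDTH = 0.1
PERCENTILE_POINTS = (70, 90, 95, 99)


@dataclass
class CumulativeHistogram:
    bin_edges: np.ndarray      # starts at 0, width 0.1
    cumulative_percent: np.ndarray  # nondecreasing, ends at 100

    def percentile_point(self, x: float) -> float:
        """Read the Xth percentile point off the binned cumulative curve
        (right edge of the first bin reaching X%)."""
        if not 0 < x < 100:
            raise ValidationError(f"percentile must lie in (0, 100); got {x}")
        idx = int(np.searchsorted(self.cumulative_percent, x, side="left"))
        idx = min(idx, self.cumulative_percent.size - 1)
        return float(self.bin_edges[idx + 1])


def build_cumulative_histogram(values: np.ndarray, bin_width: float = BIN_WIDTH) -> CumulativeHistogram:
    """Bin nCBV values from 0 at fixed width and cumulate to percent."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("empty value vector")
    if (values < 0).any():
        raise ValidationError("nCBV values must be >= 0")
    n_bins = max(int(np.floor(values.max() / bin_width)) + 1, 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    # values exactly on the last edge fall in the final bin
    counts[-1] += np.count_nonzero(values == edges[-1])
    cumulative = 100.0 * np.cumsum(counts) / values.size
    return CumulativeHistogram(bin_edges=edges, cumulative_percent=cumulative)


def percentile_point(values: np.ndarray, x: float) -> float:
    """Empirical Xth percentile with linear interpolation between order
    statistics.

    Agrees with reading the binned cumulative histogram within one bin
    width by construction; interpolation removes bin-quantization error.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("empty value vector")
    if not 0 < x < 100:
        raise ValidationError(f"percentile must lie in (0, 100); got {x}")
    return float(np.percentile(values, x, method="linear"))


def assemble_features(
    ncbv_map: Volume3D, lesion_mask: ROIMask, pro_swmri: float
) -> LesionFeatures:
    """Mean and percentile points over all fit-valid lesion voxels, plus the
    supplied proSWMRI.  Non-fittable (NaN) voxels are dropped; an all-NaN
    lesion is an error."""
    values = lesion_mask.extract(ncbv_map)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValidationError("no fit-valid voxels inside the lesion mask")
    pts = {f"ncbv{p}": percentile_point(values, p) for p in PERCENTILE_POINTS}
    return LesionFeatures(
        mean_ncbv=float(values.mean()), pro_swmri=float(pro_swmri), **pts
    )
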