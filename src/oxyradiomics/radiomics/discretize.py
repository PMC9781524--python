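"""Fixed-bin-width discretization of a biomarker map over the tumor VOI.

Values are binned on the fixed physiological range of each quantity (lower
bound anchored at the stated range minimum, not the VOI minimum), giving
``ceil((upper-lower)/bin_width)`` bins — 67 for each of the four published
range/width pairs.  Bin labels are ``floor((v - lower)/width) + 1``; a value
exactly at the upper bound is assigned the last bin.  Gray levels are the
bin numbers 1..n_bins; empty bins keep their index (fixed-bin semantics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..constants import PhysiologicalRange
from ..maps import QuantMap


@dataclass(frozen=True)
class DiscretizationSpec:
    """Fixed range and bin width, in map units."""

    lower: float
    upper: float
    bin_width: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("lower must be < upper")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")

    @property
    def n_bins(self) -> int:
        return int(np.ceil((self.upper - self.lower) / self.bin_width - 1e-12))

    @classmethod
    def from_range(cls, prange: PhysiologicalRange) -> "DiscretizationSpec":
        return cls(prange.lower, prange.upper, prange.bin_width)


@dataclass
class DiscretizedVOI:
    """Bin labels on the VOI grid plus the raw values they came from.

    ``labels`` is a 3D int array with 0 outside the effective VOI and bin
    numbers 1..n_bins inside; ``voi_mask`` marks the effective VOI (tumor
    mask ∩ map validity).  ``raw_values`` are the original in-VOI values in
    C order, matching ``labels[voi_mask]``.
    """

    labels: np.ndarray
    voi_mask: np.ndarray
    raw_values: np.ndarray
    voxel_spacing: tuple[float, float, float]
    n_bins: int

    @property
    def n_voxels(self) -> int:
        return int(self.voi_mask.sum())

    @property
    def voi_labels(self) -> np.ndarray:
        return self.labels[self.voi_mask]


def discretize(qmap: QuantMap, mask: np.ndarray, spec: DiscretizationSpec
               ) -> DiscretizedVOI:
    """Discretize the map over ``mask`` ∩ map validity.

    Voxels already invalidated by physiological-range thresholding are
    excluded entirely (they are not clamped into edge bins).
    """
    mask = np.asarray(mask, dtype=bool)
    voi = mask & qmap.valid
    # values outside [lower, upper] should not occur after range masking,
    # but guard against them rather than emitting out-of-range labels
    voi &= (qmap.values >= spec.lower) & (qmap.values <= spec.upper)
    if not np.any(voi):
        raise ValueError("empty effective VOI after masking")
    labels = np.zeros(qmap.shape, dtype=np.int64)
    inside = np.floor((qmap.values[voi] - spec.lower) / spec.bin_width).astype(np.int64) + 1
    inside = np.clip(inside, 1, spec.n_bins)      # upper bound -> last bin
    labels[voi] = inside
    return DiscretizedVOI(labels=labels, voi_mask=voi,
                          raw_values=qmap.values[voi].copy(),
                          voxel_spacing=qmap.spacing, n_bins=spec.n_bins)
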