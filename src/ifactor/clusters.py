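"""Overlap and co-localization measurements on cluster scenes.

Two clusters of different colors "co-localize" when they share at least one
pixel.  The central observable is the fraction P of *reference*-color
clusters that overlap any cluster of the other color; it is direction
dependent, whereas the overlap-region count and total overlap area are
symmetric under a channel swap.  For comparison with intensity-based
co-localization the Manders coefficients M1/M2 and the Pearson correlation
are provided as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.measure import label as cc_label

from .core import ClusterSet, IntensityGrid, ROIMask, Scene
from .errors import DataError, DegenerateImageError, NoClustersError


def rasterize(cluster_set: ClusterSet) -> np.ndarray:
    """Union of all cluster pixels as a boolean mask."""
    mask = np.zeros(cluster_set.shape, dtype=bool)
    h, w = cluster_set.shape
    for c in cluster_set:
        rows, cols = c.pixels()
        if rows.min() < 0 or cols.min() < 0 or rows.max() >= h or cols.max() >= w:
            raise DataError(f"cluster {c.id} has pixels outside the grid")
        mask[rows, cols] = True
    return mask


def overlap_mask(mask1: np.ndarray, mask2: np.ndarray) -> np.ndarray:
    """Pixel-wise intersection of two channel masks."""
    mask1 = np.asarray(mask1, dtype=bool)
    mask2 = np.asarray(mask2, dtype=bool)
    if mask1.shape != mask2.shape:
        raise DataError("mask dimensions differ")
    return mask1 & mask2


@dataclass
class OverlapStats:
    """Overlap measurements for one scene, with a fixed reference color.

    ``fraction_ref_overlapping`` is in [0, 1]; multiply by 100 for the
    percentage-of-overlap convention used in reports.  ``total_overlap_area``
    is in µm², converted as (pixel count) x (scale_nm / 1000)².
    """

    fraction_ref_overlapping: float
    n_overlap_regions: int
    total_overlap_area: float
    per_cluster_overlaps: np.ndarray
    n_ref: int
    scale: float

    @property
    def percent_overlap(self) -> float:
        return 100.0 * self.fraction_ref_overlapping


def per_cluster_overlap_flags(cluster_set: ClusterSet, other_mask: np.ndarray) -> np.ndarray:
    """Boolean flag per cluster: shares ≥ 1 pixel with ``other_mask``."""
    flags = np.empty(cluster_set.n, dtype=bool)
    for i, c in enumerate(cluster_set):
        rows, cols = c.pixels()
        flags[i] = bool(other_mask[rows, cols].any())
    return flags


def measure_overlap(scene: Scene, connectivity: int = 8) -> OverlapStats:
    """All overlap observables of a scene, reference color fixed by the scene.

    Raises :class:`NoClustersError` when the reference channel is empty —
    an undefined fraction is never silently reported as 0.
    """
    if scene.ref_set.n == 0:
        raise NoClustersError("reference channel has no clusters; overlap fraction undefined")
    other = rasterize(scene.other_set)
    flags = per_cluster_overlap_flags(scene.ref_set, other)
    omask = overlap_mask(rasterize(scene.ref_set), other)
    n_regions = int(cc_label(omask, connectivity=2 if connectivity == 8 else 1).max())
    area_um2 = float(omask.sum()) * (scene.scale / 1000.0) ** 2
    return OverlapStats(
        fraction_ref_overlapping=float(flags.mean()),
        n_overlap_regions=n_regions,
        total_overlap_area=area_um2,
        per_cluster_overlaps=flags,
        n_ref=scene.ref_set.n,
        scale=scene.scale,
    )


def manders(
    grid1: IntensityGrid,
    grid2: IntensityGrid,
    th1: float,
    th2: float,
    roi: ROIMask | None = None,
) -> tuple[float, float]:
    """Manders coefficients M1, M2 on thresholded channels inside the ROI.

    M1 = (sum of channel-1 intensities above th1 at pixels where channel 2 is
    also above th2) / (sum of all channel-1 intensities above th1); M2 is the
    symmetric quantity for channel 2.
    """
    if grid1.shape != grid2.shape:
        raise DataError("channel grids have different dimensions")
    if roi is None:
        roi = ROIMask.full(grid1.shape)
    m1_mask = (grid1.values > th1) & roi.mask
    m2_mask = (grid2.values > th2) & roi.mask
    denom1 = float(grid1.values[m1_mask].sum())
    denom2 = float(grid2.values[m2_mask].sum())
    if denom1 == 0 or denom2 == 0:
        raise DegenerateImageError("no above-threshold signal in one of the channels")
    both = m1_mask & m2_mask
    m1 = float(grid1.values[both].sum()) / denom1
    m2 = float(grid2.values[both].sum()) / denom2
    return m1, m2


def pearson(grid1: IntensityGrid, grid2: IntensityGrid, roi: ROIMask | None = None) -> float:
    """Pearson product-moment correlation of the two channels over ROI pixels."""
    if grid1.shape != grid2.shape:
        raise DataError("channel grids have different dimensions")
    if roi is None:
        roi = ROIMask.full(grid1.shape)
    v1 = grid1.values[roi.mask].astype(float)
    v2 = grid2.values[roi.mask].astype(float)
    if v1.std() == 0 or v2.std() == 0:
        raise DegenerateImageError("zero intensity variance inside ROI")
    return float(stats.pearsonr(v1, v2).statistic)
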