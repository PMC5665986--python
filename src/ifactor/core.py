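"""Core raster types shared by every module.

Conventions
-----------
* Arrays are indexed ``[row, col]`` (numpy order); a pixel's *center* sits at
  integer coordinates, pixel ``(0, 0)`` top-left.  Where user-facing x/y
  coordinates appear (polygon vertices, centroid tables) ``x`` is the column
  and ``y`` the row.
* The physical pixel pitch is carried in nm/pixel (``scale``); rendered
  single-molecule localization images are typically written at 20 nm/pixel,
  which is the default everywhere.
* A cluster is a *rigid* connected set of pixels: a fixed shape (offsets from
  the top-left corner of its bounding box) plus an anchor position.  Moving
  the anchor translates the cluster; the shape never rotates or deforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError

DEFAULT_SCALE_NM = 20.0

REFERENCE = "reference"
OTHER = "other"


@dataclass
class IntensityGrid:
    """A single-channel raster of non-negative intensities."""

    values: np.ndarray
    scale: float = DEFAULT_SCALE_NM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise DataError("intensity grid must be a non-empty 2D array")
        if not np.all(np.isfinite(self.values)):
            raise DataError("intensity grid contains non-finite values")
        if self.scale <= 0:
            raise DataError("pixel scale must be positive (nm/pixel)")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


class ROIMask:
    """Binary region-of-interest mask (True = inside).

    Identity-hashed on purpose: valid-anchor sets are cached per ROI object,
    so reusing one ``ROIMask`` across many randomizations is cheap.
    """

    def __init__(self, mask: np.ndarray):
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim != 2:
            raise DataError("ROI mask must be 2D")
        if not mask.any():
            raise DataError("ROI mask has no pixels inside")
        self.mask = mask

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "ROIMask":
        """ROI covering the whole grid (the default when none is supplied)."""
        return cls(np.ones(shape, dtype=bool))

    @classmethod
    def ellipse(
        cls,
        shape: tuple[int, int],
        semi_axes: tuple[float, float] | None = None,
        center: tuple[float, float] | None = None,
    ) -> "ROIMask":
        """Axis-aligned elliptical ROI, emulating a cell-nucleus outline.

        ``semi_axes`` is (row semi-axis, col semi-axis) in pixels; the default
        fills roughly half the frame, comparable to a nucleus in a cropped
        field of view.
        """
        h, w = shape
        if semi_axes is None:
            semi_axes = (0.45 * h, 0.35 * w)
        if center is None:
            center = ((h - 1) / 2.0, (w - 1) / 2.0)
        ry, rx = semi_axes
        yy, xx = np.mgrid[0:h, 0:w]
        inside = ((yy - center[0]) / ry) ** 2 + ((xx - center[1]) / rx) ** 2 <= 1.0
        return cls(inside)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ROIMask(shape={self.shape}, area_px={self.area_px})"


@dataclass(eq=False)
class Cluster:
    """One rigid segmented object.

    ``offsets`` is an ``(m, 2)`` integer array of ``(drow, dcol)`` shifts
    relative to the anchor, normalized so both columns have minimum 0 (the
    anchor is the top-left corner of the bounding box).
    """

    offsets: np.ndarray
    anchor: tuple[int, int]
    id: int = 0

    def __post_init__(self) -> None:
        offs = np.asarray(self.offsets, dtype=np.intp)
        if offs.ndim != 2 or offs.shape[1] != 2 or offs.shape[0] == 0:
            raise DataError("cluster shape must be a non-empty (m, 2) array")
        if offs.min() < 0 or offs[:, 0].min() != 0 or offs[:, 1].min() != 0:
            raise DataError("cluster offsets must be normalized to a top-left anchor")
        self.offsets = offs

    @property
    def area_px(self) -> int:
        return self.offsets.shape[0]

    @property
    def bbox_shape(self) -> tuple[int, int]:
        return (int(self.offsets[:, 0].max()) + 1, int(self.offsets[:, 1].max()) + 1)

    def pixels(self) -> tuple[np.ndarray, np.ndarray]:
        """Absolute (rows, cols) arrays of the cluster's pixels."""
        y, x = self.anchor
        return self.offsets[:, 0] + y, self.offsets[:, 1] + x

    def moved_to(self, anchor: tuple[int, int]) -> "Cluster":
        """Same shape and id at a new anchor (shape array shared, not copied)."""
        c = Cluster.__new__(Cluster)
        c.offsets = self.offsets
        c.anchor = (int(anchor[0]), int(anchor[1]))
        c.id = self.id
        return c

    def shape_key(self) -> bytes:
        """Hashable signature of the shape, used for anchor caching."""
        return self.offsets.tobytes()


def normalize_offsets(rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Turn absolute pixel coordinates into (offsets, top-left anchor)."""
    rows = np.asarray(rows, dtype=np.intp)
    cols = np.asarray(cols, dtype=np.intp)
    y0, x0 = int(rows.min()), int(cols.min())
    offs = np.column_stack((rows - y0, cols - x0))
    return offs, (y0, x0)


@dataclass(eq=False)
class ClusterSet:
    """An ordered collection of clusters from one color channel.

    Cluster ids are 1..n in raster-scan order of each cluster's first pixel,
    so per-cluster random-overlap probabilities stay index-aligned across
    randomizations.
    """

    clusters: list[Cluster]
    channel_label: str
    shape: tuple[int, int]
    scale: float = DEFAULT_SCALE_NM
    roi: ROIMask | None = None

    def __post_init__(self) -> None:
        if self.roi is None:
            self.roi = ROIMask.full(self.shape)
        if self.roi.shape != tuple(self.shape):
            raise DataError("ROI dimensions do not match the grid")
        h, w = self.shape
        for c in self.clusters:
            bh, bw = c.bbox_shape
            y, x = c.anchor
            if y < 0 or x < 0 or y + bh > h or x + bw > w:
                raise DataError(f"cluster {c.id} extends outside the grid")

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    @property
    def n(self) -> int:
        return len(self.clusters)

    def areas(self) -> np.ndarray:
        return np.array([c.area_px for c in self.clusters], dtype=np.intp)

    def with_clusters(self, clusters: Sequence[Cluster]) -> "ClusterSet":
        """Copy of this set with the same grid/ROI but different placements."""
        return ClusterSet(list(clusters), self.channel_label, self.shape, self.scale, self.roi)


@dataclass(eq=False)
class Scene:
    """Two cluster sets (reference + other color) sharing one grid and ROI.

    In the R-G IF convention the *green* channel is the reference: the IF is
    the interaction probability computed from the fraction of reference
    clusters that overlap the other color.
    """

    ref_set: ClusterSet
    other_set: ClusterSet
    roi: ROIMask
    scale: float = DEFAULT_SCALE_NM

    def __post_init__(self) -> None:
        if self.ref_set.shape != self.other_set.shape:
            raise DataError("channel grids have different dimensions")
        if self.ref_set.channel_label == self.other_set.channel_label:
            raise DataError("channel labels must be distinct")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ref_set.shape

    def swapped(self) -> "Scene":
        """The same scene with the reference role exchanged."""
        ref = self.other_set.with_clusters(self.other_set.clusters)
        other = self.ref_set.with_clusters(self.ref_set.clusters)
        ref.channel_label, other.channel_label = REFERENCE, OTHER
        return Scene(ref, other, self.roi, self.scale)
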