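"""Channel loading, ROI handling, Otsu thresholding and cluster extraction.

The segmentation recipe follows standard practice for rendered
single-molecule-localization images: threshold each color channel with Otsu's
method (mask rule ``value > threshold``), label connected components inside
the ROI and drop anything smaller than ``min_area`` pixels (default 4, which
removes spurious single-localization specks at 20 nm/pixel).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
import tifffile
from PIL import Image
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .core import Cluster, ClusterSet, IntensityGrid, ROIMask, normalize_offsets, DEFAULT_SCALE_NM
from .errors import DataError, DegenerateImageError

_COLOR_CHANNELS = {"r": 0, "red": 0, "g": 1, "green": 1, "b": 2, "blue": 2}


def _read_raster(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise DataError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            return np.asarray(tifffile.imread(path))
        with Image.open(path) as im:
            return np.asarray(im)
    except DataError:
        raise
    except Exception as exc:  # unreadable / truncated file
        raise DataError(f"cannot read raster image {path}: {exc}") from exc


def _select_channel(data: np.ndarray, selector: int | str) -> np.ndarray:
    """Pull one 2D channel out of a loaded raster.

    ``(H, W, C)`` with C ≤ 4 is treated as channels-last (RGB/RGBA); any other
    3D stack as pages-first (multi-page TIFF).  String selectors name RGB
    colors; integers index the channel/page axis.
    """
    if data.ndim == 2:
        n_channels = 1
    elif data.ndim == 3 and data.shape[-1] <= 4:
        n_channels = data.shape[-1]
    elif data.ndim == 3:
        n_channels = data.shape[0]
    else:
        raise DataError(f"unsupported raster shape {data.shape}")

    if isinstance(selector, str):
        key = selector.strip().lower()
        if key not in _COLOR_CHANNELS:
            raise DataError(f"unknown channel name {selector!r} (use R/G/B or an index)")
        idx = _COLOR_CHANNELS[key]
    else:
        idx = int(selector)
    if not 0 <= idx < n_channels:
        raise DataError(f"channel selector {selector!r} out of range for {n_channels} channel(s)")

    if data.ndim == 2:
        return data
    if data.ndim == 3 and data.shape[-1] <= 4:
        return data[..., idx]
    return data[idx]


def load_channels(
    image_path: str | Path,
    channel_map: tuple[int | str, int | str] = ("G", "R"),
    scale: float = DEFAULT_SCALE_NM,
) -> tuple[IntensityGrid, IntensityGrid]:
    """Read a two-channel image and return (reference, other) intensity grids.

    ``channel_map`` selects the reference channel first, e.g. ``("G", "R")``
    for the R-G IF convention (green = reference).  TIFF (single- or
    multi-page) and PNG are supported; integer bit depth is preserved.
    """
    data = _read_raster(image_path)
    ref = _select_channel(data, channel_map[0])
    other = _select_channel(data, channel_map[1])
    if ref.shape != other.shape:
        raise DataError("selected channels have mismatched dimensions")
    return IntensityGrid(ref, scale), IntensityGrid(other, scale)


def load_roi(
    source: str | Path | Sequence[Sequence[float]] | None,
    dims: tuple[int, int],
) -> ROIMask:
    """Build an ROI mask from a mask image, a polygon vertex list, or nothing.

    * ``None`` → full-grid ROI.
    * path → 8-bit mask image, nonzero = inside; must match ``dims``.
    * sequence of ``[x, y]`` vertices → filled polygon; a pixel belongs to the
      ROI when its center lies inside or on the polygon boundary.
    """
    if source is None:
        return ROIMask.full(dims)
    if isinstance(source, (str, Path)):
        data = _read_raster(source)
        if data.ndim == 3:
            data = data[..., 0] if data.shape[-1] <= 4 else data[0]
        if data.shape != tuple(dims):
            raise DataError(f"ROI mask shape {data.shape} does not match image {dims}")
        return ROIMask(data != 0)
    return polygon_roi(source, dims)


def polygon_roi(vertices: Sequence[Sequence[float]], dims: tuple[int, int]) -> ROIMask:
    """Rasterize a simple polygon given as ``[x, y]`` vertices in pixel coords."""
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise DataError("polygon ROI needs at least 3 [x, y] vertices")
    poly = shapely.Polygon(verts)
    if poly.area == 0:
        raise DataError("polygon ROI is degenerate (zero area)")
    h, w = dims
    x0 = max(0, int(np.floor(verts[:, 0].min())))
    x1 = min(w - 1, int(np.ceil(verts[:, 0].max())))
    y0 = max(0, int(np.floor(verts[:, 1].min())))
    y1 = min(h - 1, int(np.ceil(verts[:, 1].max())))
    if x1 < x0 or y1 < y0:
        raise DataError("polygon ROI lies entirely outside the grid")
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    inside = shapely.intersects_xy(poly, xx.ravel(), yy.ravel()).reshape(yy.shape)
    mask = np.zeros(dims, dtype=bool)
    mask[y0 : y1 + 1, x0 : x1 + 1] = inside
    return ROIMask(mask)


def otsu_threshold(grid: IntensityGrid, roi: ROIMask | None = None) -> float:
    """Otsu threshold of the ROI-restricted intensity histogram.

    The returned value is meant to be used with the strict mask rule
    ``values > threshold``.
    """
    if roi is None:
        roi = ROIMask.full(grid.shape)
    if roi.shape != grid.shape:
        raise DataError("ROI dimensions do not match the grid")
    values = grid.values[roi.mask]
    if np.all(values == values.flat[0]):
        raise DegenerateImageError("constant image inside ROI; Otsu threshold undefined")
    return float(threshold_otsu(values))


def segment(
    grid: IntensityGrid,
    threshold: float,
    roi: ROIMask | None = None,
    min_area: int = 4,
    connectivity: int = 8,
    channel_label: str = "reference",
) -> ClusterSet:
    """Extract the cluster set of one channel.

    Connected components of ``(values > threshold) & roi`` with the given
    pixel connectivity (8 by default, matching common ImageJ behavior);
    components smaller than ``min_area`` pixels are excluded (strictly
    "less than", so an area of exactly ``min_area`` is retained).  Clusters
    are ordered and numbered 1..n by raster-scan order of their first pixel.
    An empty result is valid (n = 0).
    """
    if roi is None:
        roi = ROIMask.full(grid.shape)
    if roi.shape != grid.shape:
        raise DataError("ROI dimensions do not match the grid")
    if connectivity not in (4, 8):
        raise DataError("connectivity must be 4 or 8")
    mask = (grid.values > threshold) & roi.mask
    return segment_mask(mask, min_area=min_area, connectivity=connectivity,
                        channel_label=channel_label, scale=grid.scale, roi=roi)


def segment_mask(
    mask: np.ndarray,
    min_area: int = 4,
    connectivity: int = 8,
    channel_label: str = "reference",
    scale: float = DEFAULT_SCALE_NM,
    roi: ROIMask | None = None,
) -> ClusterSet:
    """Label an already-binarized mask into a ClusterSet (see ``segment``)."""
    mask = np.asarray(mask, dtype=bool)
    lab = cc_label(mask, connectivity=2 if connectivity == 8 else 1)
    n_labels = int(lab.max())
    keyed: list[tuple[int, Cluster]] = []
    if n_labels:
        flat = lab.ravel()
        order = np.argsort(flat, kind="stable")
        starts = np.searchsorted(flat[order], np.arange(1, n_labels + 2))
        w = mask.shape[1]
        for lb in range(1, n_labels + 1):
            idx = order[starts[lb - 1] : starts[lb]]
            if idx.size < min_area:
                continue
            rows, cols = np.divmod(idx, w)
            offs, anchor = normalize_offsets(rows, cols)
            keyed.append((int(idx.min()), Cluster(offs, anchor)))
    clusters = [c for _, c in sorted(keyed, key=lambda t: t[0])]
    for k, c in enumerate(clusters, start=1):
        c.id = k
    return ClusterSet(clusters, channel_label, mask.shape, scale, roi)


def label_image(cluster_set: ClusterSet) -> np.ndarray:
    """16-bit label image: 0 = background, k = cluster id."""
    img = np.zeros(cluster_set.shape, dtype=np.uint16)
    for c in cluster_set:
        rows, cols = c.pixels()
        img[rows, cols] = c.id
    return img


def write_label_image(cluster_set: ClusterSet, path: str | Path) -> None:
    tifffile.imwrite(Path(path), label_image(cluster_set))


def cluster_table(cluster_set: ClusterSet):
    """Per-cluster summary table (id, area, centroid, bounding box)."""
    rows = []
    for c in cluster_set:
        ys, xs = c.pixels()
        bh, bw = c.bbox_shape
        rows.append(
            {
                "id": c.id,
                "area_px": c.area_px,
                "centroid_x": float(xs.mean()),
                "centroid_y": float(ys.mean()),
                "bbox_x": int(xs.min()),
                "bbox_y": int(ys.min()),
                "bbox_w": bw,
                "bbox_h": bh,
            }
        )
    import pandas as pd

    return pd.DataFrame(rows, columns=["id", "area_px", "centroid_x", "centroid_y",
                                       "bbox_x", "bbox_y", "bbox_w", "bbox_h"])
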