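"""Random cluster placement: the null model and IF-biased placement.

The null model translates every cluster, rigidly and without rotation, to a
uniformly random position where the whole cluster lies inside the ROI.
Interaction is injected with an accept/retry rule applied per reference
cluster against the already-placed other-color mask:

1. draw a uniformly random in-ROI position;
2. if the interaction factor f is 0, keep it;
3. otherwise, if the cluster overlaps (≥ 1 shared pixel) the other color,
   keep it;
4. if it does not overlap, draw u ~ U[0, 1) and keep when u > f, else go
   back to step 1.

Summing the resulting geometric series gives the per-cluster overlap
probability p_k(f) = p_k(0) / (1 - (1 - p_k(0)) f), where p_k(0) is the
random-overlap probability — the closed form the estimator inverts.

Uniform draws over a cluster's valid-anchor set are implemented by rejection
sampling from the ROI bounding box (exactly uniform over the valid set, with
no per-shape precomputation); exhaustive enumeration of the valid-anchor set
is available through :func:`valid_anchors` and used as a fallback when
rejection fails to find any valid position.
"""

from __future__ import annotations

from dataclasses import dataclass
from weakref import WeakKeyDictionary

import numpy as np

from .core import Cluster, ClusterSet, ROIMask, Scene
from .clusters import rasterize
from .errors import PlacementError

# per-ROI cache of enumerated valid-anchor sets, keyed by cluster shape
_anchor_cache: "WeakKeyDictionary[ROIMask, dict]" = WeakKeyDictionary()
_bbox_cache: "WeakKeyDictionary[ROIMask, tuple[int, int, int, int]]" = WeakKeyDictionary()

_REJECTION_TRIES = 5_000


@dataclass
class PlacementConfig:
    """Parameters of IF-biased placement.

    ``f`` is the interaction factor in [0, 1].  ``randomize_both`` chooses
    between randomizing both colors (the full null) and keeping the other
    color fixed at its original positions (e.g. membrane-bound species).
    ``max_attempts_per_cluster`` bounds the accept/retry loop, which is
    otherwise unbounded as f → 1 when overlap is unreachable.
    """

    f: float = 0.0
    randomize_both: bool = True
    max_attempts_per_cluster: int = 10_000
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("interaction factor f must be in [0, 1]")
        if self.max_attempts_per_cluster < 1:
            raise ValueError("max_attempts_per_cluster must be >= 1")


def _roi_bbox(roi: ROIMask) -> tuple[int, int, int, int]:
    """Inclusive (y0, y1, x0, x1) bounding box of the ROI's true pixels."""
    cached = _bbox_cache.get(roi)
    if cached is None:
        rows = np.flatnonzero(roi.mask.any(axis=1))
        cols = np.flatnonzero(roi.mask.any(axis=0))
        cached = (int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1]))
        _bbox_cache[roi] = cached
    return cached


class _ShapeDraw:
    """Per-(cluster shape, ROI) sampling state for uniform anchor draws."""

    __slots__ = ("offs_flat", "ylo", "yhi", "xlo", "xhi", "w", "ok")

    def __init__(self, cluster: Cluster, roi: ROIMask, containment: bool):
        h, w = roi.shape
        bh, bw = cluster.bbox_shape
        y0, y1, x0, x1 = _roi_bbox(roi)
        self.w = w
        self.offs_flat = (cluster.offsets[:, 0] * w + cluster.offsets[:, 1]) if containment else None
        self.ylo, self.xlo = y0, x0
        if containment:
            self.yhi = min(y1 - bh + 1, h - bh)
            self.xhi = min(x1 - bw + 1, w - bw)
        else:
            self.yhi = min(y1, h - bh)
            self.xhi = min(x1, w - bw)
        self.ok = self.yhi >= self.ylo and self.xhi >= self.xlo


def _draw(shape: _ShapeDraw, roi_flat: np.ndarray, rng: np.random.Generator) -> tuple[int, int] | None:
    """One uniform draw from the valid-anchor set, or None if rejection fails."""
    if not shape.ok:
        return None
    ylo, yhi, xlo, xhi, w = shape.ylo, shape.yhi, shape.xlo, shape.xhi, shape.w
    offs = shape.offs_flat
    for _ in range(_REJECTION_TRIES):
        y = int(rng.integers(ylo, yhi + 1))
        x = int(rng.integers(xlo, xhi + 1))
        if offs is None:
            if roi_flat[y * w + x]:
                return y, x
        elif roi_flat[offs + (y * w + x)].all():
            return y, x
    return None


def valid_anchors(cluster: Cluster, roi: ROIMask, containment: bool = True) -> np.ndarray:
    """Exhaustively enumerate all anchors where the cluster lies in the ROI.

    Returns an ``(k, 2)`` array of (row, col) anchors.  With
    ``containment=True`` (default) every cluster pixel must be inside the
    ROI; with ``containment=False`` only the anchor pixel must be, though
    the cluster must still fit inside the grid.  Cached per (ROI object,
    cluster shape); intended for verification and as the fallback when
    rejection sampling finds no valid position.
    """
    key = (cluster.shape_key(), containment)
    per_roi = _anchor_cache.setdefault(roi, {})
    cached = per_roi.get(key)
    if cached is not None:
        return cached
    h, w = roi.shape
    bh, bw = cluster.bbox_shape
    nh, nw = h - bh + 1, w - bw + 1
    if nh <= 0 or nw <= 0:
        anchors = np.empty((0, 2), dtype=np.intp)
    else:
        if containment:
            valid = np.ones((nh, nw), dtype=bool)
            for dy, dx in cluster.offsets:
                valid &= roi.mask[dy : dy + nh, dx : dx + nw]
        else:
            valid = roi.mask[:nh, :nw]
        rows, cols = np.nonzero(valid)
        anchors = np.empty((rows.size, 2), dtype=np.intp)
        anchors[:, 0] = rows
        anchors[:, 1] = cols
    per_roi[key] = anchors
    return anchors


def draw_anchor(
    cluster: Cluster,
    roi: ROIMask,
    rng: np.random.Generator,
    containment: bool = True,
    _shape: _ShapeDraw | None = None,
) -> tuple[int, int]:
    """One anchor drawn uniformly from the cluster's valid-anchor set."""
    shape = _shape if _shape is not None else _ShapeDraw(cluster, roi, containment)
    pos = _draw(shape, roi.mask.ravel(), rng)
    if pos is None:
        anchors = valid_anchors(cluster, roi, containment)
        if anchors.shape[0] == 0:
            raise PlacementError(f"cluster {cluster.id} has no valid anchor inside the ROI")
        i = int(rng.integers(anchors.shape[0]))
        pos = (int(anchors[i, 0]), int(anchors[i, 1]))
    return pos


def place_random(
    cluster_set: ClusterSet,
    roi: ROIMask | None = None,
    rng: np.random.Generator | None = None,
    containment: bool = True,
) -> ClusterSet:
    """Uniformly random rigid placement of every cluster inside the ROI.

    Each cluster's anchor is drawn uniformly from its valid-anchor set;
    shapes are never rotated or deformed, and same-color clusters are
    allowed to overlap each other.
    """
    roi = roi if roi is not None else cluster_set.roi
    rng = rng if rng is not None else np.random.default_rng()
    roi_flat = roi.mask.ravel()
    placed = []
    for c in cluster_set:
        shape = _ShapeDraw(c, roi, containment)
        pos = _draw(shape, roi_flat, rng)
        if pos is None:
            pos = draw_anchor(c, roi, rng, containment, _shape=shape)
        placed.append(c.moved_to(pos))
    return cluster_set.with_clusters(placed)


def place_cluster_with_if(
    cluster: Cluster,
    other_mask: np.ndarray,
    roi: ROIMask,
    f: float,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
    containment: bool = True,
) -> tuple[Cluster, bool, bool]:
    """Place one cluster by the accept/retry rule described in the module docs.

    Returns ``(placed cluster, overlapped, exhausted)``.  ``exhausted`` is
    True when ``max_attempts`` random positions were tried without an
    accepting draw (possible only when f is near 1 and overlap is
    unreachable in practice); the last position is then kept.
    """
    shape = _ShapeDraw(cluster, roi, containment)
    roi_flat = roi.mask.ravel()
    other_flat = np.ascontiguousarray(other_mask).ravel()
    w = roi.shape[1]
    offs_flat = cluster.offsets[:, 0] * w + cluster.offsets[:, 1]
    pos = None
    for _ in range(max_attempts):
        pos = _draw(shape, roi_flat, rng)
        if pos is None:
            pos = draw_anchor(cluster, roi, rng, containment, _shape=shape)
        y, x = pos
        overlapped = bool(other_flat[offs_flat + (y * w + x)].any())
        if f == 0.0 or overlapped:
            return cluster.moved_to(pos), overlapped, False
        if rng.random() > f:
            return cluster.moved_to(pos), False, False
    return cluster.moved_to(pos), False, True


def place_with_if(
    ref_set: ClusterSet,
    other_mask: np.ndarray,
    roi: ROIMask | None = None,
    cfg: PlacementConfig | None = None,
    rng: np.random.Generator | None = None,
    containment: bool = True,
) -> tuple[ClusterSet, int]:
    """Place every reference cluster with IF-elevated overlap probability.

    Returns the placed set and the number of clusters whose retry loop hit
    ``max_attempts_per_cluster`` (kept at their last position; nonzero
    counts signal a pathological configuration such as f = 1 with an empty
    other channel).
    """
    roi = roi if roi is not None else ref_set.roi
    cfg = cfg if cfg is not None else PlacementConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    placed = []
    exhausted = 0
    for c in ref_set:
        pc, _, ex = place_cluster_with_if(
            c, other_mask, roi, cfg.f, rng, cfg.max_attempts_per_cluster, containment
        )
        exhausted += ex
        placed.append(pc)
    return ref_set.with_clusters(placed), exhausted


def randomize_scene(
    scene: Scene,
    cfg: PlacementConfig | None = None,
    rng: np.random.Generator | None = None,
    containment: bool = True,
) -> Scene:
    """Re-place a whole scene: other color first, then the reference color.

    The other-color set is placed uniformly at random when
    ``cfg.randomize_both`` (else kept at its original positions); the
    reference set is then placed against the resulting other-color mask with
    interaction factor ``cfg.f``.
    """
    cfg = cfg if cfg is not None else PlacementConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    if cfg.randomize_both:
        other = place_random(scene.other_set, scene.roi, rng, containment)
    else:
        other = scene.other_set
    other_mask = rasterize(other)
    ref, exhausted = place_with_if(scene.ref_set, other_mask, scene.roi, cfg, rng, containment)
    if exhausted:
        import warnings

        warnings.warn(
            f"{exhausted} cluster(s) exhausted max placement attempts "
            f"(f={cfg.f}); kept at last random position",
            stacklevel=2,
        )
    return Scene(ref, other, scene.roi, scene.scale)
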