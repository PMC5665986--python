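import numpy as np
import pytest

from ifactor.core import Cluster, ClusterSet, ROIMask, Scene, REFERENCE, OTHER, normalize_offsets


def cluster_from_pixels(pixels, cid=0):
    """Build a Cluster from a list of absolute (row, col) pixels."""
    rows, cols = zip(*pixels)
    offs, anchor = normalize_offsets(np.array(rows), np.array(cols))
    return Cluster(offs, anchor, cid)


def block(y0, x0, h, w, cid=0):
    """Rectangular cluster covering rows [y0, y0+h) x cols [x0, x0+w)."""
    return cluster_from_pixels(
        [(y, x) for y in range(y0, y0 + h) for x in range(x0, x0 + w)], cid
    )


def make_scene(ref_clusters, other_clusters, shape=(20, 20), roi=None, scale=20.0):
    roi = roi if roi is not None else ROIMask.full(shape)
    for k, c in enumerate(ref_clusters, 1):
        c.id = k
    for k, c in enumerate(other_clusters, 1):
        c.id = k
    ref = ClusterSet(list(ref_clusters), REFERENCE, shape, scale, roi)
    other = ClusterSet(list(other_clusters), OTHER, shape, scale, roi)
    return Scene(ref, other, roi, scale)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_scene():
    """Hand-enumerable 20x20 scene: 3 reference clusters, 2 of which overlap
    the other channel; the overlap mask has 2 components totaling 13 px."""
    ref = [
        block(2, 2, 3, 3),     # overlaps other X in exactly 1 px at (4, 4)
        block(10, 10, 4, 4),   # overlaps other Y in a 4x3 = 12 px patch
        block(2, 14, 2, 2),    # no overlap
    ]
    other = [
        block(4, 4, 3, 3),     # X
        block(10, 10, 4, 3),   # Y (subset of ref B's columns)
    ]
    return make_scene(ref, other)
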