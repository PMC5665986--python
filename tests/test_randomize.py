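"""Null-model and IF-biased placement."""

import numpy as np
import pytest
from scipy import stats

from ifactor.core import ROIMask
from ifactor.clusters import rasterize
from ifactor.errors import PlacementError
from ifactor.randomize import (
    PlacementConfig,
    place_cluster_with_if,
    place_random,
    place_with_if,
    randomize_scene,
    valid_anchors,
)

from conftest import block, cluster_from_pixels, make_scene


def brute_force_anchors(cluster, roi):
    """Oracle: double loop over every anchor, checking full containment."""
    h, w = roi.shape
    out = []
    for y in range(h):
        for x in range(w):
            rows = cluster.offsets[:, 0] + y
            cols = cluster.offsets[:, 1] + x
            if rows.max() < h and cols.max() < w and roi.mask[rows, cols].all():
                out.append((y, x))
    return out


class TestValidAnchors:
    def test_matches_brute_force_on_l_shaped_roi(self):
        mask = np.zeros((12, 12), bool)
        mask[2:10, 2:6] = True
        mask[6:10, 2:11] = True  # L shape
        roi = ROIMask(mask)
        c = cluster_from_pixels([(0, 0), (0, 1), (1, 0)])
        got = {tuple(a) for a in valid_anchors(c, roi)}
        assert got == set(brute_force_anchors(c, roi))

    def test_anchor_only_mode_is_larger(self):
        roi = ROIMask.ellipse((20, 20), semi_axes=(6, 6))
        c = block(0, 0, 3, 3)
        full = valid_anchors(c, roi, containment=True)
        loose = valid_anchors(c, roi, containment=False)
        assert loose.shape[0] > full.shape[0]


class TestPlaceRandom:
    def test_uniform_over_valid_anchors(self):
        # 1-px cluster in a 10x10 rectangular ROI inside a larger grid
        mask = np.zeros((16, 16), bool)
        mask[3:13, 2:12] = True
        roi = ROIMask(mask)
        scene = make_scene([block(0, 0, 1, 1)], [block(0, 0, 1, 1)], shape=(16, 16), roi=roi)
        rng = np.random.default_rng(123)
        counts = np.zeros((16, 16))
        n_draws = 20_000
        for _ in range(n_draws):
            placed = place_random(scene.ref_set, roi, rng)
            counts[placed.clusters[0].anchor] += 1
        assert counts[~mask].sum() == 0
        observed = counts[mask]
        chi2 = ((observed - n_draws / 100) ** 2 / (n_draws / 100)).sum()
        p = stats.chi2.sf(chi2, df=99)
        assert p > 0.01

    def test_cluster_equal_to_roi_is_deterministic(self, rng):
        roi = ROIMask.ellipse((15, 15), semi_axes=(5, 5))
        rows, cols = np.nonzero(roi.mask)
        c = cluster_from_pixels(list(zip(rows, cols)))
        scene = make_scene([c], [block(0, 0, 1, 1)], shape=(15, 15), roi=roi)
        placed = place_random(scene.ref_set, roi, rng)
        assert placed.clusters[0].anchor == (int(rows.min()), int(cols.min()))

    def test_shape_and_area_preserved(self, rng):
        roi = ROIMask.full((30, 30))
        clusters = [block(0, 0, 2, 3), block(5, 5, 4, 1), cluster_from_pixels([(0, 0), (1, 1), (2, 2), (3, 3)])]
        scene = make_scene(clusters, [block(0, 0, 1, 1)], shape=(30, 30), roi=roi)
        placed = place_random(scene.ref_set, roi, rng)
        assert sorted(c.area_px for c in placed) == sorted(c.area_px for c in scene.ref_set)
        for before, after in zip(scene.ref_set, placed):
            assert np.array_equal(before.offsets, after.offsets)
        assert rasterize(placed) is not None  # all pixels inside the grid

    def test_oversized_cluster_raises(self, rng):
        roi = ROIMask.ellipse((10, 10), semi_axes=(3, 3))
        c = block(0, 0, 9, 9)
        scene = make_scene([c], [block(0, 0, 1, 1)], shape=(10, 10), roi=roi)
        with pytest.raises(PlacementError):
            place_random(scene.ref_set, roi, rng)


class TestPlaceWithIF:
    def test_f_zero_identical_to_place_random(self):
        roi = ROIMask.ellipse((40, 40), semi_axes=(15, 15))
        clusters = [block(0, 0, 2, 2, cid=k) for k in range(1, 6)]
        scene = make_scene(clusters, [block(0, 0, 3, 3)], shape=(40, 40), roi=roi)
        other_mask = rasterize(scene.other_set)
        a = place_random(scene.ref_set, roi, np.random.default_rng(7))
        b, exhausted = place_with_if(scene.ref_set, other_mask, roi,
                                     PlacementConfig(f=0.0), np.random.default_rng(7))
        assert exhausted == 0
        assert [c.anchor for c in a] == [c.anchor for c in b]

    def test_f_one_always_overlaps_when_reachable(self):
        roi = ROIMask.full((12, 12))
        other_mask = np.zeros((12, 12), bool)
        other_mask[4:8, 4:8] = True
        scene = make_scene([block(0, 0, 2, 2, cid=k) for k in range(1, 9)],
                           [block(4, 4, 4, 4)], shape=(12, 12), roi=roi)
        placed, exhausted = place_with_if(scene.ref_set, other_mask, roi,
                                          PlacementConfig(f=1.0), np.random.default_rng(3))
        assert exhausted == 0
        for c in placed:
            rows, cols = c.pixels()
            assert other_mask[rows, cols].any()

    def test_unreachable_overlap_exhausts_with_warning_count(self):
        roi = ROIMask.full((10, 10))
        other_mask = np.zeros((10, 10), bool)  # empty: overlap impossible
        scene = make_scene([block(0, 0, 1, 1), block(2, 2, 1, 1)],
                           [block(5, 5, 1, 1)], shape=(10, 10), roi=roi)
        placed, exhausted = place_with_if(
            scene.ref_set, other_mask, roi,
            PlacementConfig(f=1.0, max_attempts_per_cluster=50),
            np.random.default_rng(0),
        )
        assert exhausted == 2
        assert len(placed.clusters) == 2  # kept at last positions

    def test_invalid_f_rejected(self):
        with pytest.raises(ValueError):
            PlacementConfig(f=1.5)


class TestRandomizeScene:
    def test_same_seed_bit_identical(self, toy_scene):
        cfg = PlacementConfig(f=0.5)
        a = randomize_scene(toy_scene, cfg, np.random.default_rng(11))
        b = randomize_scene(toy_scene, cfg, np.random.default_rng(11))
        for sa, sb in ((a.ref_set, b.ref_set), (a.other_set, b.other_set)):
            assert [c.anchor for c in sa] == [c.anchor for c in sb]

    def test_area_multiset_conserved(self, toy_scene, rng):
        out = randomize_scene(toy_scene, PlacementConfig(f=0.9), rng)
        assert sorted(out.ref_set.areas()) == sorted(toy_scene.ref_set.areas())
        assert sorted(out.other_set.areas()) == sorted(toy_scene.other_set.areas())

    def test_all_pixels_inside_roi(self):
        roi = ROIMask.ellipse((30, 30), semi_axes=(10, 10))
        scene = make_scene([block(0, 0, 2, 3)], [block(0, 0, 3, 2)], shape=(30, 30), roi=roi)
        out = randomize_scene(scene, PlacementConfig(f=0.0), np.random.default_rng(5))
        for cset in (out.ref_set, out.other_set):
            for c in cset:
                rows, cols = c.pixels()
                assert roi.mask[rows, cols].all()

    def test_fixed_other_channel(self, toy_scene, rng):
        cfg = PlacementConfig(f=0.0, randomize_both=False)
        out = randomize_scene(toy_scene, cfg, rng)
        assert [c.anchor for c in out.other_set] == [c.anchor for c in toy_scene.other_set]
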