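"""Channel loading, ROI construction, Otsu thresholding and segmentation."""

import json

import numpy as np
import pytest
import tifffile
from PIL import Image

from ifactor.core import IntensityGrid, ROIMask
from ifactor.errors import DataError, DegenerateImageError
from ifactor.segmentation import (
    cluster_table,
    label_image,
    load_channels,
    load_roi,
    otsu_threshold,
    polygon_roi,
    segment,
    segment_mask,
)
from ifactor.clusters import rasterize


def brute_force_otsu(values):
    """Independent oracle: exhaustive search of the threshold maximizing
    between-class variance, mask rule value > t."""
    values = np.asarray(values).ravel()
    best_t, best_var = None, -1.0
    for t in np.unique(values)[:-1]:
        fg = values[values > t]
        bg = values[values <= t]
        w1, w0 = fg.size / values.size, bg.size / values.size
        var = w0 * w1 * (fg.mean() - bg.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestLoadChannels:
    def test_rgb_png_extracts_named_channels(self, tmp_path):
        rgb = np.zeros((12, 15, 3), dtype=np.uint8)
        rgb[..., 0] = 7   # red
        rgb[..., 1] = 99  # green
        path = tmp_path / "img.png"
        Image.fromarray(rgb).save(path)
        green, red = load_channels(path, ("G", "R"))
        assert green.shape == red.shape == (12, 15)
        assert np.all(green.values == 99) and np.all(red.values == 7)

    def test_multipage_tiff_pages(self, tmp_path):
        pages = np.stack([np.full((8, 9), 3, np.uint16), np.full((8, 9), 11, np.uint16)])
        path = tmp_path / "stack.tif"
        tifffile.imwrite(path, pages)
        g0, g1 = load_channels(path, (0, 1))
        assert np.all(g0.values == 3) and np.all(g1.values == 11)
        assert g1.values.dtype == np.uint16  # bit depth preserved

    def test_single_channel_image_rejects_second_channel(self, tmp_path):
        path = tmp_path / "gray.tif"
        tifffile.imwrite(path, np.zeros((5, 5), np.uint8))
        with pytest.raises(DataError):
            load_channels(path, (0, 1))

    def test_missing_file(self, tmp_path):
        with pytest.raises(DataError):
            load_channels(tmp_path / "nope.tif", (0, 1))


class TestROI:
    def test_rectangle_polygon_area(self):
        # closed rectangle (0,0)-(9,9): pixel centers 0..9 in both axes
        roi = polygon_roi([[0, 0], [9, 0], [9, 9], [0, 9]], (20, 20))
        assert roi.area_px == 100
        assert roi.mask[:10, :10].all() and not roi.mask[10:, :].any()

    def test_absent_roi_is_full_grid(self):
        roi = load_roi(None, (6, 7))
        assert roi.area_px == 42

    def test_all_false_mask_rejected(self, tmp_path):
        path = tmp_path / "roi.png"
        Image.fromarray(np.zeros((6, 7), np.uint8)).save(path)
        with pytest.raises(DataError):
            load_roi(path, (6, 7))

    def test_mask_image_roundtrip(self, tmp_path):
        mask = np.zeros((6, 7), np.uint8)
        mask[2:4, 1:5] = 255
        path = tmp_path / "roi.png"
        Image.fromarray(mask).save(path)
        roi = load_roi(path, (6, 7))
        assert roi.area_px == 8

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(DataError):
            polygon_roi([[0, 0], [5, 5], [10, 10]], (20, 20))


class TestOtsu:
    def test_bimodal_matches_brute_force(self, rng):
        values = np.full(200, 10, dtype=float)
        values[:20] = 200.0
        rng.shuffle(values)
        grid = IntensityGrid(values.reshape(10, 20))
        th = otsu_threshold(grid)
        assert 10 <= th < 200
        oracle = brute_force_otsu(values)
        # both thresholds must separate the two populations identically
        assert np.array_equal(grid.values > th, grid.values > oracle)
        assert (grid.values > th).sum() == 20

    def test_binary_image_mask_selects_foreground(self):
        values = np.zeros((8, 8))
        values[2:4, 2:6] = 255
        th = otsu_threshold(IntensityGrid(values))
        assert np.array_equal(values > th, values == 255)

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(IntensityGrid(np.full((5, 5), 3.0)))

    def test_roi_restriction_changes_histogram(self):
        values = np.zeros((10, 10))
        values[:5] = 100.0  # constant inside the lower-half ROI
        roi = ROIMask(np.arange(10)[:, None] >= np.full(10, 5))
        with pytest.raises(DegenerateImageError):
            otsu_threshold(IntensityGrid(values), roi)


class TestSegment:
    def _grid_with_blobs(self):
        values = np.zeros((8, 8))
        values[1:2, 1:6] = 10  # area 5
        values[5:6, 1:4] = 10  # area 3
        return IntensityGrid(values)

    def test_min_area_excludes_small_blob(self):
        cs = segment(self._grid_with_blobs(), threshold=5)
        assert cs.n == 1
        assert cs.clusters[0].area_px == 5

    def test_area_exactly_four_retained(self):
        values = np.zeros((8, 8))
        values[2:4, 2:4] = 9
        cs = segment(IntensityGrid(values), threshold=5)
        assert cs.n == 1 and cs.clusters[0].area_px == 4

    def test_diagonal_connectivity(self):
        # X of 2-px diagonal pairs: one 4-px cluster under 8-conn,
        # two sub-threshold 2-px components under 4-conn
        values = np.zeros((8, 8))
        for y, x in [(2, 2), (3, 3), (2, 4), (3, 5)]:
            values[y, x] = 9
        cs8 = segment(IntensityGrid(values), 5, connectivity=8)
        cs4 = segment(IntensityGrid(values), 5, connectivity=4)
        assert cs8.n == 1 and cs8.clusters[0].area_px == 4
        assert cs4.n == 0

    def test_empty_result_is_valid(self):
        cs = segment(IntensityGrid(np.zeros((5, 5))), threshold=1)
        assert cs.n == 0

    def test_scan_order_ids(self):
        values = np.zeros((10, 10))
        values[6:8, 1:4] = 9   # later in scan order
        values[1:3, 5:8] = 9   # first
        cs = segment(IntensityGrid(values), 5)
        assert [c.id for c in cs] == [1, 2]
        assert cs.clusters[0].anchor == (1, 5)
        assert cs.clusters[1].anchor == (6, 1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_idempotent_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        values = (rng.random((30, 30)) < 0.3).astype(float)
        cs = segment(IntensityGrid(values), 0.5)
        re_cs = segment_mask(rasterize(cs))
        assert re_cs.n == cs.n
        for a, b in zip(cs, re_cs):
            assert a.anchor == b.anchor
            assert np.array_equal(a.offsets, b.offsets)
        # no retained cluster below the filter, total area bounded by mask
        assert all(c.area_px >= 4 for c in cs)
        assert sum(c.area_px for c in cs) <= int((values > 0.5).sum())

    def test_roi_clips_clusters(self):
        values = np.zeros((8, 8))
        values[0:8, 2:4] = 9  # vertical bar crossing the ROI boundary
        roi = ROIMask(np.arange(8)[:, None] < np.full(8, 4))
        cs = segment(IntensityGrid(values), 5, roi)
        assert cs.n == 1
        assert cs.clusters[0].area_px == 8  # 4 rows x 2 cols inside ROI


class TestExports:
    def test_label_image_and_table(self):
        values = np.zeros((10, 10))
        values[1:3, 1:4] = 9
        values[6:9, 5:7] = 9
        cs = segment(IntensityGrid(values), 5)
        img = label_image(cs)
        assert img.dtype == np.uint16
        assert set(np.unique(img)) == {0, 1, 2}
        tab = cluster_table(cs)
        assert list(tab.id) == [1, 2]
        assert list(tab.area_px) == [6, 6]
        assert tab.loc[0, "bbox_x"] == 1 and tab.loc[0, "bbox_y"] == 1
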