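"""Superpixel partitioning, blue removal, cluster selection, mask assembly."""

import numpy as np
import pytest
from skimage.draw import disk
from skimage.morphology import dilation
from skimage.segmentation import find_boundaries

from gazelabel import (
    SegmentationParams,
    annotate_frame,
    assemble_mask,
    build_attention_area,
    cluster_select,
    dice,
    remove_blue,
    segment_superpixels,
    superpixel_count,
)
from gazelabel.segmentation import SuperpixelPatch


def _patch_from_features(rgb255_rows, counts, sat=None):
    """Hand-built SuperpixelPatch with given mean colors and pixel counts."""
    rgb = np.asarray(rgb255_rows, dtype=float) / 255.0
    n = len(rgb)
    sat = np.asarray(sat if sat is not None else [0.5] * n, dtype=float)
    hue = np.zeros(n)
    feats = np.column_stack([rgb, hue, sat])
    return SuperpixelPatch(
        labels=np.zeros((1, 1), dtype=int),
        n_superpixels=n,
        features=feats,
        pixel_counts=np.asarray(counts, dtype=np.int64),
        excluded=np.zeros(n, dtype=bool),
    )


class TestSuperpixelCount:
    @pytest.mark.parametrize(
        "area, size, expected",
        [
            (180 * 180, 900, 36),
            (960 * 544, 900, 580),  # round(580.27)
            (900, 900, 2),  # clamped: K-means needs at least two items
            (100, 900, 2),
        ],
    )
    def test_ratio_rounded_and_clamped(self, area, size, expected):
        assert superpixel_count(area, size) == expected

    @pytest.mark.parametrize("area, size", [(0, 900), (900, 0), (-1, 900)])
    def test_non_positive_rejected(self, area, size):
        with pytest.raises(ValueError):
            superpixel_count(area, size)


class TestSegmentSuperpixels:
    def test_partition_covers_patch_exactly(self):
        rng = np.random.default_rng(0)
        patch_img = rng.integers(0, 255, size=(90, 90, 3), dtype=np.uint8)
        patch = segment_superpixels(patch_img, 9, SegmentationParams())
        assert patch.pixel_counts.sum() == 90 * 90
        assert patch.features.shape == (patch.n_superpixels, 5)
        assert set(np.unique(patch.labels)) == set(range(patch.n_superpixels))

    def test_constant_patch_degenerates_to_single_segment(self):
        patch_img = np.full((60, 60, 3), 77, dtype=np.uint8)
        patch = segment_superpixels(patch_img, 4, SegmentationParams())
        assert patch.degenerate
        assert patch.n_superpixels == 1

    def test_two_tone_boundary_respected(self):
        """Superpixels should not straddle a strong vertical color edge."""
        img = np.zeros((120, 120, 3), dtype=np.uint8)
        img[:, :60] = (200, 40, 40)
        img[:, 60:] = (40, 160, 60)
        patch = segment_superpixels(img, 16, SegmentationParams())
        straddle = 0
        for s in range(patch.n_superpixels):
            left = int((patch.labels[:, :60] == s).sum())
            right = int((patch.labels[:, 60:] == s).sum())
            straddle += min(left, right)
        assert straddle / img[..., 0].size < 0.02

    def test_apple_boundary_recall(self):
        """Superpixel edges trace a shaded apple's outline (2 px tolerance)."""
        rng = np.random.default_rng(5)
        img = np.zeros((180, 180, 3), float)
        img[...] = (55, 100, 45)
        img += rng.normal(0, 6, img.shape)
        rr, cc = disk((90, 90), 17, shape=(180, 180))
        rho = np.hypot(rr - 90, cc - 90) / 17
        shade = 0.72 + 0.28 * np.sqrt(np.clip(1 - rho**2, 0, 1))
        img[rr, cc] = np.asarray((190.0, 45.0, 40.0))[None, :] * shade[:, None]
        img = np.clip(img, 0, 255).astype(np.uint8)

        gt = np.zeros((180, 180), bool)
        gt[rr, cc] = True
        patch = segment_superpixels(img, 36, SegmentationParams())
        sp_edges = find_boundaries(patch.labels, mode="thick")
        sp_edges = dilation(sp_edges, np.ones((5, 5), bool))  # 2 px tolerance
        apple_edge = find_boundaries(gt, mode="inner")
        recall = (sp_edges & apple_edge).sum() / apple_edge.sum()
        assert recall >= 0.8


class TestRemoveBlue:
    def test_relational_rule(self):
        patch = _patch_from_features(
            [(0, 0, 255), (200, 30, 30), (135, 206, 235), (100, 100, 105)],
            [10, 10, 10, 10],
        )
        remove_blue(patch, blue_margin=10)
        assert patch.excluded.tolist() == [True, False, True, False]

    def test_half_blue_pixels_also_excluded(self):
        patch = _patch_from_features([(120, 150, 150)], [100])
        patch.blue_fraction = np.array([0.6])
        remove_blue(patch, blue_margin=10)
        assert patch.excluded[0]

    def test_excluded_pixels_never_in_mask(self):
        img = np.zeros((120, 120, 3), dtype=np.uint8)
        img[:, :, :] = (60, 110, 50)
        img[:40] = (135, 206, 235)  # sky strip
        rr, cc = disk((80, 60), 15, shape=(120, 120))
        img[rr, cc] = (200, 40, 40)
        area = build_attention_area((60, 60), (120, 120), 120)
        mask, patches, _ = annotate_frame(img, [area])
        blue_px = (img[..., 2].astype(int) > img[..., 0] + 10) & (
            img[..., 2].astype(int) > img[..., 1] + 10
        )
        assert not (mask.raster & blue_px).any()


class TestClusterSelect:
    def test_smaller_cluster_returned(self):
        feats = [(60, 110, 50)] * 30 + [(200, 40, 40)] * 6
        patch = _patch_from_features(feats, [900] * 36)
        sel = cluster_select(patch, SegmentationParams())
        assert sel == set(range(30, 36))

    def test_smaller_by_pixel_area_not_count(self):
        # 3 big background superpixels vs 5 tiny apple ones
        feats = [(60, 110, 50)] * 3 + [(200, 40, 40)] * 5
        patch = _patch_from_features(feats, [5000] * 3 + [200] * 5)
        sel = cluster_select(patch, SegmentationParams())
        assert sel == {3, 4, 5, 6, 7}

    def test_fully_excluded_patch_gives_empty_selection_with_warning(self):
        patch = _patch_from_features([(0, 0, 255)] * 4, [100] * 4)
        remove_blue(patch)
        with pytest.warns(UserWarning, match="non-excluded"):
            assert cluster_select(patch, SegmentationParams()) == set()

    def test_selected_area_never_exceeds_unselected(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            n = int(rng.integers(4, 40))
            feats = rng.uniform(0, 255, size=(n, 3))
            counts = rng.integers(100, 2000, size=n)
            patch = _patch_from_features(feats, counts)
            sel = cluster_select(patch, SegmentationParams(seed=trial))
            sel_area = patch.pixel_counts[sorted(sel)].sum()
            assert sel_area <= patch.pixel_counts.sum() - sel_area


class TestAssembleMask:
    def test_no_areas_all_false(self):
        mask = assemble_mask([], [], [], (100, 80))
        assert mask.raster.shape == (80, 100)
        assert not mask.raster.any()

    def test_selected_superpixel_popcount_maps_back(self):
        area = build_attention_area((50, 50), (200, 200), 60)
        labels = np.zeros((60, 60), dtype=int)
        labels[:15] = 1  # 900 px superpixel
        patch = SuperpixelPatch(
            labels=labels, n_superpixels=2,
            features=np.zeros((2, 5)), pixel_counts=np.array([2700, 900]),
            excluded=np.zeros(2, dtype=bool),
        )
        mask = assemble_mask([area], [patch], [{1}], (200, 200))
        assert int(mask.raster.sum()) == 900

    def test_disjoint_areas_union_adds(self):
        a1 = build_attention_area((30, 30), (300, 300), 60)
        a2 = build_attention_area((200, 200), (300, 300), 60)
        labels = np.zeros((60, 60), dtype=int)
        labels[:10, :10] = 1
        patch = SuperpixelPatch(
            labels=labels, n_superpixels=2,
            features=np.zeros((2, 5)), pixel_counts=np.array([3500, 100]),
            excluded=np.zeros(2, dtype=bool),
        )
        mask = assemble_mask([a1, a2], [patch, patch], [{1}, {1}], (300, 300))
        assert int(mask.raster.sum()) == 200

    def test_mask_confined_to_area_union(self):
        area = build_attention_area((90, 90), (400, 400), 180)
        rng = np.random.default_rng(1)
        img = rng.integers(0, 255, (400, 400, 3), dtype=np.uint8)
        mask, _, _ = annotate_frame(img, [area])
        outside = np.ones((400, 400), bool)
        x0, y0, x1, y1 = area.box
        outside[y0:y1, x0:x1] = False
        assert not (mask.raster & outside).any()


class TestEndToEnd:
    def test_red_apple_on_green_recovered(self):
        rng = np.random.default_rng(2)
        img = np.zeros((180, 180, 3), float)
        img[...] = (60, 110, 50)
        img += rng.normal(0, 5, img.shape)
        rr, cc = disk((90, 95), 16, shape=(180, 180))
        img[rr, cc] = (195, 45, 40)
        img = np.clip(img, 0, 255).astype(np.uint8)
        gt = np.zeros((180, 180), bool)
        gt[rr, cc] = True
        area = build_attention_area((90, 90), (180, 180), 180)
        mask, _, _ = annotate_frame(img, [area])
        assert dice(mask, gt) >= 0.7

    def test_annotate_frame_deterministic(self, default_scene):
        area = build_attention_area((480, 272), default_scene.frame_size, 180)
        m1, _, _ = annotate_frame(default_scene.image, [area], SegmentationParams(seed=9))
        m2, _, _ = annotate_frame(default_scene.image, [area], SegmentationParams(seed=9))
        assert np.array_equal(m1.raster, m2.raster)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(apple_size=0)
        with pytest.raises(ValueError):
            SegmentationParams(k_clusters=1)
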