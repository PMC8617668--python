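import numpy as np
import pytest

from skywatch.geometry import BBox, Detection, GroundTruthBox, iou
from skywatch.preprocess import (
    AnchorSet,
    TileLayout,
    estimate_anchors,
    map_detection_to_global,
    map_detection_to_network,
    merge_tile_detections,
    stack_sequence,
    temporal_stack,
    tile_annotations,
    tile_frame,
    translate_tile_detection,
)


class TestTileLayout:
    def test_default_is_four_full_hd_tiles(self):
        layout = TileLayout()
        assert (layout.tile_w, layout.tile_h) == (1920, 1080)
        assert layout.grid_rows * layout.grid_cols == 4

    def test_inexact_partition_rejected(self):
        with pytest.raises(ValueError):
            TileLayout(frame_w=1001, frame_h=540, grid_cols=2, grid_rows=2)


class TestTileFrame:
    def test_default_4k_layout(self):
        frame = np.zeros((2160, 3840), dtype=np.uint8)
        tiles = tile_frame(frame)
        assert len(tiles) == 4
        assert all(t.shape == (1080, 1920) for t, _, _ in tiles)

    def test_reassembly_is_bit_exact(self, rng):
        layout = TileLayout(frame_w=96, frame_h=54, grid_cols=3, grid_rows=2)
        frame = rng.integers(0, 256, (54, 96), dtype=np.uint8)
        rebuilt = np.zeros_like(frame)
        for tile, r, c in tile_frame(frame, layout):
            rebuilt[
                r * layout.tile_h : (r + 1) * layout.tile_h,
                c * layout.tile_w : (c + 1) * layout.tile_w,
            ] = tile
        assert np.array_equal(rebuilt, frame)

    def test_row_major_order_on_2x2(self):
        frame = np.array([[1, 2], [3, 4]], dtype=np.uint8)
        layout = TileLayout(frame_w=2, frame_h=2)
        tiles = tile_frame(frame, layout)
        assert [int(t[0, 0]) for t, _, _ in tiles] == [1, 2, 3, 4]
        assert [(r, c) for _, r, c in tiles] == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tile_frame(np.zeros((100, 100)), TileLayout())


class TestCoordinateMapping:
    def test_origin_maps_to_origin(self):
        d = Detection(BBox(0.0001, 0.0001, 10, 10), 0.9)
        g = map_detection_to_global(d, 0, 0)
        assert (g.box.x, g.box.y) == pytest.approx((0.0001 * 1920 / 1024, 0.0001 * 1080 / 1024))

    def test_network_to_global_arithmetic(self):
        # centre of the 1024 network input of tile (row 0, col 1)
        d = Detection(BBox(512, 512, 64, 64), 0.8)
        g = map_detection_to_global(d, 0, 1)
        assert g.box.x == pytest.approx(1920 + 512 * 1920 / 1024)  # 2880
        assert g.box.y == pytest.approx(512 * 1080 / 1024)  # 540
        assert g.box.w == pytest.approx(120.0)
        assert g.box.h == pytest.approx(67.5)
        assert g.confidence == 0.8

    def test_round_trip_identity(self, rng):
        layout = TileLayout()
        for _ in range(50):
            r = int(rng.integers(0, 2))
            c = int(rng.integers(0, 2))
            box = BBox(
                c * 1920 + rng.uniform(0, 1800),
                r * 1080 + rng.uniform(0, 1000),
                rng.uniform(1, 100),
                rng.uniform(1, 70),
            )
            d = Detection(box, 0.5)
            n = map_detection_to_network(d, r, c, layout)
            back = map_detection_to_global(n, r, c, layout)
            for attr in ("x", "y", "w", "h"):
                assert getattr(back.box, attr) == pytest.approx(
                    getattr(box, attr), abs=1e-9
                )

    def test_out_of_grid_tile_rejected(self):
        d = Detection(BBox(0, 0, 10, 10), 0.9)
        with pytest.raises(ValueError):
            map_detection_to_global(d, 2, 0)

    def test_translate_only_mapping(self):
        d = Detection(BBox(5, 6, 10, 10), 1.0)
        g = translate_tile_detection(d, 1, 1)
        assert (g.box.x, g.box.y, g.box.w) == (1925, 1086, 10)


class TestMergeTileDetections:
    def test_all_empty(self):
        assert merge_tile_detections([[], [], [], []]) == []

    def test_plain_concatenation_by_default(self):
        d1 = Detection(BBox(0, 0, 10, 10), 0.9)
        d2 = Detection(BBox(2000, 0, 10, 10), 0.8)
        assert merge_tile_detections([[d1], [d2]]) == [d1, d2]

    def test_boundary_duplicates_kept_without_nms(self):
        d1 = Detection(BBox(1910, 100, 20, 20), 0.9)
        d2 = Detection(BBox(1912, 100, 20, 20), 0.8)
        assert len(merge_tile_detections([[d1], [d2]])) == 2

    def test_nms_suppresses_near_duplicates(self):
        d1 = Detection(BBox(1910, 100, 20, 20), 0.9)
        d2 = Detection(BBox(1912, 100, 20, 20), 0.8)
        assert iou(d1.box, d2.box) > 0.5
        merged = merge_tile_detections([[d1], [d2]], cross_tile_nms_iou=0.5)
        assert merged == [d1]


class TestTemporalStacking:
    def test_identical_frames_fill_all_channels(self):
        f = np.arange(12, dtype=np.uint8).reshape(3, 4)
        stack = temporal_stack(f, f, f)
        for ch in range(3):
            assert np.array_equal(stack.channels[..., ch], f)

    def test_center_channel_is_current_frame(self, rng):
        frames = [rng.integers(0, 256, (8, 8), dtype=np.uint8) for _ in range(3)]
        stack = temporal_stack(*frames)
        assert np.array_equal(stack.cur, frames[1])

    def test_bird_only_in_center_channel(self):
        sky = np.full((20, 20), 200, dtype=np.uint8)
        cur = sky.copy()
        cur[5:8, 5:8] = 140
        stack = temporal_stack(sky, cur, sky)
        assert np.array_equal(stack.prev, stack.next)
        diff = stack.prev.astype(int) - stack.cur.astype(int)
        assert np.all(diff[5:8, 5:8] == 60)
        assert np.count_nonzero(diff) == 9

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            temporal_stack(np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((5, 4)))

    @pytest.mark.parametrize("n", [3, 5, 10])
    def test_sequence_yields_n_minus_two_stacks(self, n, rng):
        frames = [rng.integers(0, 256, (6, 6), dtype=np.uint8) for _ in range(n)]
        stacks = stack_sequence(frames)
        assert len(stacks) == n - 2
        for s in stacks:
            assert np.array_equal(s.cur, frames[s.center_index])
        assert [s.center_index for s in stacks] == list(range(1, n - 1))

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            stack_sequence([np.zeros((4, 4))] * 2)


class TestAnchorEstimation:
    def test_recovers_planted_clusters(self, rng):
        centers = [(4, 5), (8, 7), (12, 12), (10, 16), (20, 18), (24, 30),
                   (40, 32), (50, 55), (80, 120)]
        gts = []
        for w, h in centers:
            for _ in range(10):
                gts.append(
                    GroundTruthBox(
                        BBox(0, 0, w + rng.uniform(-0.3, 0.3), h + rng.uniform(-0.3, 0.3))
                    )
                )
        anchors = estimate_anchors(gts, k=9, seed=0)
        got = sorted(anchors.anchors, key=lambda wh: wh[0] * wh[1])
        want = sorted(centers, key=lambda wh: wh[0] * wh[1])
        for (gw, gh), (ww, wh_) in zip(got, want):
            assert abs(gw - ww) <= 1 and abs(gh - wh_) <= 1

    def test_degenerate_identical_boxes(self):
        gts = [GroundTruthBox(BBox(0, 0, 10, 14)) for _ in range(20)]
        anchors = estimate_anchors(gts, k=9, seed=0)
        assert all(pair == (10, 14) for pair in anchors.anchors)

    def test_contract_nine_pairs_sorted_by_area(self, rng):
        gts = [
            GroundTruthBox(BBox(0, 0, rng.uniform(2, 100), rng.uniform(2, 100)))
            for _ in range(60)
        ]
        anchors = estimate_anchors(gts, k=9, seed=3)
        areas = [w * h for w, h in anchors.anchors]
        assert len(anchors.anchors) == 9
        assert areas == sorted(areas)

    def test_deterministic_given_seed(self, rng):
        gts = [
            GroundTruthBox(BBox(0, 0, rng.uniform(2, 100), rng.uniform(2, 100)))
            for _ in range(40)
        ]
        assert estimate_anchors(gts, seed=5) == estimate_anchors(gts, seed=5)

    def test_too_few_boxes_rejected(self):
        gts = [GroundTruthBox(BBox(0, 0, 5, 5)) for _ in range(5)]
        with pytest.raises(ValueError):
            estimate_anchors(gts, k=9)


class TestAnnotationTiling:
    def test_interior_boxes_become_tile_local(self):
        layout = TileLayout()
        g = GroundTruthBox(BBox(2000, 1200, 30, 30))
        per_tile, dropped = tile_annotations([g], layout)
        assert dropped == 0
        (local,) = per_tile[(1, 1)]
        assert (local.box.x, local.box.y) == (80, 120)

    def test_boundary_straddlers_dropped(self):
        layout = TileLayout()
        g = GroundTruthBox(BBox(1910, 100, 30, 30))  # crosses x=1920
        per_tile, dropped = tile_annotations([g], layout)
        assert dropped == 1
        assert all(len(v) == 0 for v in per_tile.values())
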