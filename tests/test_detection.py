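import itertools

import numpy as np
import pytest

from wildcount.detection import (
    DetectConfig,
    Segment,
    binarize,
    label_segments,
    clusters_for_segment,
    split_segment,
    detect_from_probmap,
    detect_scene,
    count_with_ci,
)
from wildcount.scene import Scene
from wildcount.synthetic import SceneSpec, generate_scene, generate_oracle_probmap


def _scene(size=32, ps=0.5):
    return Scene(np.zeros((4, size, size), dtype=np.uint16), ps,
                 origin=(0.0, size * ps))


class TestBinarize:
    def test_tie_at_threshold_is_positive(self):
        p = np.array([[0.5, 0.49], [0.51, 0.0]])
        np.testing.assert_array_equal(binarize(p, 0.5),
                                      [[1, 0], [1, 0]])

    def test_degenerate_thresholds(self):
        p = np.random.default_rng(0).random((5, 5))
        assert binarize(np.zeros((3, 3)), 0.5).sum() == 0
        assert binarize(p, 0.0).sum() == 25

    def test_threshold_monotonicity(self):
        p = np.random.default_rng(1).random((16, 16))
        counts = [int(binarize(p, t).sum()) for t in np.linspace(0.05, 0.95, 10)]
        assert (np.diff(counts) <= 0).all()


class TestSegments:
    def test_diagonal_pixels_8_vs_4_connectivity(self):
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[1, 1] = mask[2, 2] = 1
        assert len(label_segments(mask, connectivity=8)) == 1
        assert len(label_segments(mask, connectivity=4)) == 2

    def test_empty_mask(self):
        assert label_segments(np.zeros((4, 4), dtype=np.uint8)) == []

    def test_ceiling_rule(self):
        assert clusters_for_segment(9) == 1
        assert clusters_for_segment(10) == 2
        assert clusters_for_segment(1) == 1
        assert clusters_for_segment(18) == 2
        assert clusters_for_segment(19) == 3


class TestSplitSegment:
    def test_symmetric_block_centroid(self):
        pixels = np.array(list(itertools.product(range(3), range(3))))
        seg = Segment(pixels + [5, 7], id=1)
        (center,) = split_segment(seg, 1)
        np.testing.assert_allclose(center, [6, 8])

    def test_single_pixel(self):
        (center,) = split_segment(Segment(np.array([[4, 9]]), 1), 1)
        np.testing.assert_allclose(center, [4, 9])

    def test_k_larger_than_pixels_rejected(self):
        with pytest.raises(ValueError, match="cannot split"):
            split_segment(Segment(np.array([[0, 0]]), 1), 2)

    def test_matches_exhaustive_kmeans_on_small_segments(self):
        # brute-force oracle: best k-partition by exhaustive assignment
        def exhaustive_inertia(pts, k):
            best = np.inf
            for assign in itertools.product(range(k), repeat=len(pts)):
                if len(set(assign)) < k:
                    continue
                cost = 0.0
                for j in range(k):
                    members = pts[np.array(assign) == j]
                    cost += ((members - members.mean(axis=0)) ** 2).sum()
                best = min(best, cost)
            return best

        rng = np.random.default_rng(0)
        for trial in range(5):
            # two 2x2 blocks bridged by one pixel: 9 px, enumerable exactly
            base = rng.integers(0, 10, size=2)
            blk = np.array(list(itertools.product(range(2), range(2))))
            pts = np.vstack([blk + base, blk + base + [0, 4],
                             [[base[0], base[1] + 2]]]).astype(float)
            for k in (2, 3):
                centers = split_segment(Segment(pts, 1), k, seed=trial)
                assign = np.argmin(
                    ((pts[:, None, :] - centers[None]) ** 2).sum(-1), axis=1
                )
                inertia = sum(
                    ((pts[assign == j] - centers[j]) ** 2).sum() for j in range(k)
                )
                assert inertia == pytest.approx(exhaustive_inertia(pts, k),
                                                rel=1e-6)

    def test_deterministic_under_seed(self):
        pts = np.random.default_rng(3).integers(0, 20, size=(15, 2)).astype(float)
        seg = Segment(pts, 1)
        np.testing.assert_allclose(split_segment(seg, 2, seed=9),
                                   split_segment(seg, 2, seed=9))


class TestDetectFromProbmap:
    def test_perfect_oracle_recovers_all_points(self):
        spec = SceneSpec(width_px=96, height_px=96, n_animals=20,
                         min_separation_px=5.0, seed=11)
        scene, gt = generate_scene(spec)
        prob = generate_oracle_probmap(gt, scene, noise_level=0.0)
        pred = detect_from_probmap(prob, scene)
        assert len(pred) == 20
        # each detection lands on a ground-truth pixel center
        d = np.hypot(
            *(pred.points[:, None, :] - gt.points[None]).transpose(2, 0, 1)
        ).min(axis=1)
        assert d.max() < 1e-6

    def test_empty_map_gives_no_points(self):
        scene = _scene()
        pred = detect_from_probmap(np.zeros((32, 32), dtype=np.float32), scene)
        assert len(pred) == 0

    def test_count_conservation_through_splitting(self):
        rng = np.random.default_rng(5)
        scene = _scene(48)
        mask = (rng.random((48, 48)) < 0.1).astype(np.float32)
        pred = detect_from_probmap(mask, scene)
        segs = label_segments(binarize(mask, 0.5))
        expected = sum(clusters_for_segment(len(s.pixels)) for s in segs)
        assert len(pred) == expected

    def test_small_segments_emit_exactly_one_point(self):
        scene = _scene(16)
        prob = np.zeros((16, 16), dtype=np.float32)
        prob[2:5, 2:5] = 1.0  # 9 px
        prob[10:12, 10:12] = 1.0  # 4 px
        pred = detect_from_probmap(prob, scene)
        assert len(pred) == 2

    def test_adjacent_animals_split_by_ceiling_rule(self):
        # two 3x3 blocks one pixel apart merge into 18 px -> 2 points
        scene = _scene(16)
        prob = np.zeros((16, 16), dtype=np.float32)
        prob[4:7, 2:5] = 1.0
        prob[4:7, 6:9] = 1.0
        mask = binarize(prob, 0.5)
        assert len(label_segments(mask)) == 2  # gap of one column
        prob[4:7, 5] = 1.0  # bridge -> single 21-px segment -> k = 3
        pred = detect_from_probmap(prob, scene)
        assert len(pred) == 3


class TestDetectScene:
    def test_oracle_predictor_end_to_end(self):
        spec = SceneSpec(width_px=96, height_px=96, n_animals=15,
                         min_separation_px=5.0, seed=21)
        scene, gt = generate_scene(spec)
        prob = generate_oracle_probmap(gt, scene, noise_level=0.0)

        def oracle_predictor(image):
            return prob  # scene is a single tile

        pred = detect_scene(scene, oracle_predictor, patch_px=96)
        assert len(pred) == 15

    def test_blob_straddling_tile_seam(self):
        # 3x3 block across the boundary between two 16-px tiles
        scene = _scene(32)
        prob = np.zeros((32, 32), dtype=np.float32)
        prob[8:11, 15:18] = 1.0
        tiles = {}

        def predictor(image):
            # return the oracle window for whichever tile is requested
            key = predictor.calls
            predictor.calls += 1
            r0 = (key // 2) * 16
            c0 = (key % 2) * 16
            return prob[r0 : r0 + 16, c0 : c0 + 16]

        predictor.calls = 0
        pred = detect_scene(scene, predictor, patch_px=16)
        assert 1 <= len(pred) <= 2  # documented seam behavior


class TestCountCI:
    def test_constant_runs_zero_width(self):
        est = count_with_ci([100, 100, 100])
        assert est.mean_count == 100
        assert est.half_width_95 == 0

    def test_t_interval_closed_form(self):
        est = count_with_ci([1, 2, 3, 4, 5])
        assert est.mean_count == pytest.approx(3.0)
        # t(0.975, 4) * sd / sqrt(5) = 2.776 * 1.5811 / 2.2361
        assert est.half_width_95 == pytest.approx(1.963, abs=1e-3)

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            count_with_ci([42])

    def test_normal_flag_narrows_interval(self):
        t_est = count_with_ci([10, 12, 14, 11, 13], use_t=True)
        z_est = count_with_ci([10, 12, 14, 11, 13], use_t=False)
        assert z_est.half_width_95 < t_est.half_width_95
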