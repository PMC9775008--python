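"""Detector components: losses, offsets, anchors, assignment, suppression."""

import numpy as np
import pytest

from pollenstage import detect, synth
from pollenstage.detect import (
    IGNORE,
    NEGATIVE,
    AnchorGrid,
    Detection,
    DetectorConfig,
    assign_anchors,
    decode_offsets,
    encode_offsets,
    focal_loss,
    iou_matrix,
    nms,
    regression_loss,
    smooth_l1,
)


class TestFocalLoss:
    def test_perfect_prediction_is_zero(self):
        for gamma in (0.0, 0.5, 2.0, 5.0):
            assert focal_loss(1.0, gamma) == 0.0

    def test_gamma_zero_is_cross_entropy(self):
        assert focal_loss(0.5, gamma=0.0) == pytest.approx(np.log(2), abs=1e-12)

    def test_direct_evaluation(self):
        assert focal_loss(0.5, gamma=2.0) == pytest.approx(0.25 * np.log(2), abs=1e-6)

    def test_nonpositive_pt_clamped_not_error(self):
        assert np.isfinite(focal_loss(0.0, 2.0))
        assert np.isfinite(focal_loss(-0.3, 2.0))

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(0.5, gamma=-1.0)

    def test_monotone_decreasing_and_below_cross_entropy(self, rng):
        """FL is strictly decreasing in pt and never above plain CE for
        gamma > 0 (the down-weighting of easy examples)."""
        pts = np.sort(rng.uniform(0.01, 0.99, size=300))
        for gamma in (0.5, 2.0):
            vals = focal_loss(pts, gamma)
            assert (np.diff(vals) < 0).all()
            assert (vals <= focal_loss(pts, 0.0) + 1e-12).all()

    def test_trainer_gradient_matches_finite_differences(self, rng):
        z = rng.normal(0, 2, size=(40, 3))
        t = (rng.random((40, 3)) < 0.3).astype(float)
        _, grad = detect._focal_grad(z, t, gamma=2.0, alpha=0.5)
        eps = 1e-6
        for i, j in [(0, 0), (5, 1), (17, 2), (39, 0)]:
            zp, zm = z.copy(), z.copy()
            zp[i, j] += eps
            zm[i, j] -= eps
            lp, _ = detect._focal_grad(zp, t, 2.0, 0.5)
            lm, _ = detect._focal_grad(zm, t, 2.0, 0.5)
            assert grad[i, j] == pytest.approx((lp[i, j] - lm[i, j]) / (2 * eps), abs=1e-6)


class TestSmoothL1:
    def test_zero_at_origin(self):
        assert smooth_l1(0.0) == 0.0

    def test_branch_continuity_at_one(self):
        assert smooth_l1(1.0) == pytest.approx(0.5)
        assert smooth_l1(-1.0) == pytest.approx(0.5)
        assert smooth_l1(1.0 - 1e-9) == pytest.approx(0.5, abs=1e-8)

    def test_linear_branch(self):
        assert smooth_l1(3.0) == pytest.approx(2.5)

    def test_even_and_monotone(self, rng):
        xs = rng.normal(0, 3, size=500)
        assert np.allclose(smooth_l1(xs), smooth_l1(-xs))
        order = np.sort(np.abs(xs))
        assert (np.diff(smooth_l1(order)) >= 0).all()


class TestOffsets:
    def test_box_equals_anchor_gives_zero(self):
        anchor = (10, 10, 50, 70)
        assert np.allclose(encode_offsets(anchor, anchor), 0.0)

    def test_double_width_log_two(self):
        anchor = (0, 0, 40, 40)
        box = (-20, 0, 60, 40)  # same center/height, twice the width
        t = encode_offsets(anchor, box)
        assert t[2] == pytest.approx(np.log(2))
        assert t[0] == pytest.approx(0.0)

    def test_roundtrip_thousand_random_boxes(self, rng):
        anchors = np.stack([
            rng.uniform(0, 100, 1000), rng.uniform(0, 100, 1000),
            rng.uniform(110, 200, 1000), rng.uniform(110, 200, 1000)], axis=1)
        boxes = np.stack([
            rng.uniform(0, 100, 1000), rng.uniform(0, 100, 1000),
            rng.uniform(110, 200, 1000), rng.uniform(110, 200, 1000)], axis=1)
        back = decode_offsets(anchors, encode_offsets(anchors, boxes))
        assert np.abs(back - boxes).max() < 1e-6

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            encode_offsets((0, 0, 0, 10), (0, 0, 5, 5))
        with pytest.raises(ValueError):
            decode_offsets((0, 0, 10, 0), (0, 0, 0, 0))


class TestRegressionLoss:
    def test_perfect_regression_zero(self):
        v = (10, 10, 40, 40)
        assert regression_loss(v, v, (8, 8, 44, 44)) == 0.0

    def test_single_unit_offset(self):
        anchor = (0.0, 0.0, 10.0, 10.0)
        gt = (0.0, 0.0, 10.0, 10.0)
        pred = decode_offsets(anchor, [1.0, 0.0, 0.0, 0.0])
        assert regression_loss(pred, gt, anchor) == pytest.approx(0.5)

    def test_four_linear_branch_terms(self):
        anchor = (0.0, 0.0, 10.0, 10.0)
        gt = (0.0, 0.0, 10.0, 10.0)
        pred = decode_offsets(anchor, [2.0, 2.0, 2.0, 2.0])
        assert regression_loss(pred, gt, anchor) == pytest.approx(4 * 1.5)

    def test_degenerate_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            regression_loss((0, 0, 5, 5), (0, 0, 0, 5), (0, 0, 5, 5))


class TestAssignAnchors:
    def test_identical_anchor_positive(self):
        gt = np.array([[10, 10, 50, 50]])
        out = assign_anchors(gt, gt)
        assert out[0] == 0

    def test_no_ground_truth_all_negative(self, rng):
        anchors = rng.uniform(0, 100, size=(20, 2))
        anchors = np.concatenate([anchors, anchors + 10], axis=1)
        assert (assign_anchors(anchors, np.zeros((0, 4))) == NEGATIVE).all()

    def test_three_band_rule(self):
        gt = [(0, 0, 100, 100)]
        anchors = np.array([
            [0, 0, 100, 30],     # IoU 0.3 -> negative
            [0, 0, 100, 45],     # IoU 0.45 -> ignore
            [0, 0, 100, 60],     # IoU 0.6 -> positive
        ], float)
        out = assign_anchors(anchors, gt, pos_thr=0.5, neg_thr=0.4)
        assert out[0] == NEGATIVE
        assert out[1] == IGNORE
        assert out[2] == 0

    def test_best_anchor_fallback(self):
        """A ground truth below both thresholds still claims its best anchor."""
        gt = [(0, 0, 100, 100)]
        anchors = np.array([[0, 0, 100, 20], [0, 0, 100, 25]], float)  # IoU .2/.25
        out = assign_anchors(anchors, gt, pos_thr=0.5, neg_thr=0.4)
        assert out[1] == 0
        assert out[0] == NEGATIVE

    def test_threshold_order_enforced(self):
        with pytest.raises(ValueError):
            assign_anchors(np.zeros((0, 4)), np.zeros((0, 4)), pos_thr=0.3, neg_thr=0.5)


def _nms_oracle(boxes, scores, thr):
    """Quadratic reference suppression."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    keep, dead = [], set()
    for i in order:
        if i in dead:
            continue
        keep.append(i)
        for j in order:
            if j not in dead and j != i:
                if iou_matrix(boxes[i], boxes[j])[0, 0] >= thr:
                    dead.add(j)
    return keep


class TestNms:
    def test_duplicate_boxes_highest_score_survives(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10]], float)
        assert nms(boxes, [0.8, 0.9], 0.5).tolist() == [1]

    def test_disjoint_boxes_all_survive(self):
        boxes = np.array([[0, 0, 10, 10], [20, 20, 30, 30], [50, 0, 60, 10]], float)
        assert sorted(nms(boxes, [0.5, 0.9, 0.7], 0.5)) == [0, 1, 2]

    def test_matches_quadratic_oracle(self, rng):
        for trial in range(100):
            n = int(rng.integers(1, 26))
            xy = rng.uniform(0, 80, size=(n, 2))
            wh = rng.uniform(5, 40, size=(n, 2))
            boxes = np.concatenate([xy, xy + wh], axis=1)
            scores = rng.random(n)
            thr = float(rng.uniform(0.2, 0.7))
            assert nms(boxes, scores, thr).tolist() == _nms_oracle(boxes, scores, thr)


class TestAnchorGrid:
    def test_anchor_count_formula(self):
        grid = AnchorGrid()
        total = 0
        for lev, stride in enumerate(grid.strides):
            fh, fw = 256 // stride, 256 // stride
            anchors = grid.level_anchors(lev, fh, fw)
            assert len(anchors) == fh * fw * grid.anchors_per_cell
            total += len(anchors)
        assert total == sum(
            (256 // s) ** 2 * grid.anchors_per_cell for s in grid.strides
        )

    def test_aspect_ratios_realized(self):
        grid = AnchorGrid()
        anchors = grid.level_anchors(0, 2, 2)
        w = anchors[:, 2] - anchors[:, 0]
        h = anchors[:, 3] - anchors[:, 1]
        ratios = np.unique(np.round(h / w, 3))
        assert set(ratios) == {0.5, 1.0, 2.0}

    def test_no_fusion_grid_is_single_level(self):
        cfg = DetectorConfig(fusion=False)
        assert len(cfg.effective_grid().strides) == 1


class TestDetectionType:
    def test_invalid_boxes_and_scores_rejected(self):
        with pytest.raises(ValueError):
            Detection((10, 0, 5, 5), 0.5, "pollen")
        with pytest.raises(ValueError):
            Detection((0, 0, 5, 5), 1.5, "pollen")


def _untrained_model(fusion=True):
    """A fresh model with prior-only weights: scores everything ~0.01."""
    cfg = DetectorConfig(fusion=fusion, hidden=0)
    nf = 25
    w_cls = np.zeros((nf + 1, cfg.effective_grid().anchors_per_cell * 3))
    w_cls[-1, :] = -np.log(99.0)
    w_reg = np.zeros((nf + 1, cfg.effective_grid().anchors_per_cell * 4))
    return detect.DetectorModel(cfg, np.zeros((0, 0)), w_cls, w_reg,
                                np.zeros(nf, np.float32), np.ones(nf, np.float32))


class TestDetectRegions:
    def test_blank_patch_empty(self):
        blank = np.full((256, 256, 3), 238, np.uint8)
        assert detect.detect_regions(blank, _untrained_model(), score_thr=0.5) == []

    def test_score_threshold_one_empty(self, small_slide):
        slide, _ = small_slide
        patch = slide.pixels[:256, :256]
        assert detect.detect_regions(patch, _untrained_model(), score_thr=1.0) == []

    def test_no_fusion_model_single_scale(self):
        model = _untrained_model(fusion=False)
        assert model.n_levels == 1
        assert _untrained_model(fusion=True).n_levels == 3


class TestCropRegions:
    def test_full_patch_detection_one_crop(self, small_slide):
        slide, _ = small_slide
        patch = slide.pixels[:256, :256]
        det = Detection((0.0, 0.0, 256.0, 256.0), 0.9, "pollen")
        crops = detect.crop_regions(patch, [det], out_size=100)
        assert len(crops) == 1
        assert crops[0].image.shape == (100, 100, 3)

    def test_empty_detections_empty_output(self, small_slide):
        slide, _ = small_slide
        assert detect.crop_regions(slide.pixels[:256, :256], []) == []

    def test_non_pollen_classes_skipped(self, small_slide):
        slide, _ = small_slide
        det = Detection((0, 0, 50, 50), 0.9, "impurity")
        assert detect.crop_regions(slide.pixels[:256, :256], [det]) == []

    def test_out_of_bounds_box_clipped_with_provenance(self, small_slide):
        slide, _ = small_slide
        patch = slide.pixels[:256, :256]
        det = Detection((-40.0, 100.0, 40.0, 180.0), 0.9, "pollen")
        crops = detect.crop_regions(patch, [det], out_size=100)
        assert len(crops) == 1
        assert crops[0].box == (0.0, 100.0, 40.0, 180.0)

    def test_fully_outside_box_skipped_with_warning(self, small_slide):
        slide, _ = small_slide
        patch = slide.pixels[:256, :256]
        det = Detection((300.0, 300.0, 340.0, 340.0), 0.9, "pollen")
        with pytest.warns(UserWarning, match="zero area"):
            assert detect.crop_regions(patch, [det]) == []


class TestModelPersistence:
    def test_save_load_same_scores(self, tmp_path, small_corpus):
        d2 = synth.build_d2(small_corpus)
        cfg = DetectorConfig(seed=0, epochs=3, hidden=8)
        model = detect.train_detector(d2, cfg)
        path = tmp_path / "det.npz"
        model.save(path)
        loaded = detect.DetectorModel.load(path)
        patch = small_corpus[0][0].pixels[:256, :256]
        a = detect.detect_regions(patch, model, score_thr=0.05)
        b = detect.detect_regions(patch, loaded, score_thr=0.05)
        assert [(d.box, d.score, d.coarse) for d in a] == [(d.box, d.score, d.coarse) for d in b]

    def test_same_seed_same_loss(self, small_corpus):
        d2 = synth.build_d2(small_corpus)
        cfg = DetectorConfig(seed=5, epochs=3, hidden=8)
        m1 = detect.train_detector(d2, cfg)
        m2 = detect.train_detector(d2, cfg)
        assert m1.train_loss == m2.train_loss

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            detect.train_detector([])
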