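"""Region detector: anchors, box coding, proposal filtering, NMS, RoI
pooling, the multitask loss, training behavior, and cell labeling."""

import numpy as np
import pytest

from rbcdetect import (
    AnchorSpec,
    Detection,
    DetectionFilterConfig,
    ProposalConfig,
    RBCDetector,
    box_iou_matrix,
    decode_boxes,
    encode_boxes,
    filter_detections,
    filter_proposals,
    generate_anchors,
    label_cells,
    multitask_loss,
    nms,
    roi_pool,
    train_detector,
)


def brute_force_nms(boxes, scores, iou_threshold):
    """O(n^2) reference: accept in score order, reject on overlap with any
    accepted box."""
    order = np.argsort(-scores, kind="stable")
    kept = []
    for i in order:
        ok = True
        for j in kept:
            if box_iou_matrix(boxes[i : i + 1], boxes[j : j + 1])[0, 0] > iou_threshold:
                ok = False
                break
        if ok:
            kept.append(int(i))
    return kept


def naive_roi_pool(fm, roi, oh, ow):
    """Per-bin max oracle on a single-channel map."""
    x0, y0, x1, y1 = int(np.floor(roi[0])), int(np.floor(roi[1])), int(np.ceil(roi[2])), int(np.ceil(roi[3]))
    xe = np.floor(np.linspace(x0, x1, ow + 1)).astype(int)
    ye = np.floor(np.linspace(y0, y1, oh + 1)).astype(int)
    out = np.zeros((oh, ow))
    for i in range(oh):
        for j in range(ow):
            block = fm[ye[i] : ye[i + 1], xe[j] : xe[j + 1]]
            out[i, j] = block.max() if block.size else 0.0
    return out


class TestAnchors:
    def test_anchor_count(self):
        a = generate_anchors((64, 64), AnchorSpec(stride=8, scales=(12, 20), ratios=(1.0,)))
        assert a.shape == (128, 4)

    def test_unit_ratio_square(self):
        a = generate_anchors((8, 8), AnchorSpec(stride=8, scales=(20,), ratios=(1.0,)))
        assert np.allclose(a[:, 2] - a[:, 0], 20) and np.allclose(a[:, 3] - a[:, 1], 20)

    def test_ratio_preserves_area(self):
        a = generate_anchors((8, 8), AnchorSpec(stride=8, scales=(16,), ratios=(2.0,)))
        w, h = a[0, 2] - a[0, 0], a[0, 3] - a[0, 1]
        assert w * h == pytest.approx(16**2)
        assert w / h == pytest.approx(2.0)

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            AnchorSpec(scales=())


class TestBoxCoding:
    def test_zero_deltas_reproduce_anchors(self):
        anchors = generate_anchors((32, 32), AnchorSpec())
        assert np.array_equal(decode_boxes(anchors, np.zeros((len(anchors), 4))), anchors)

    def test_tx_shifts_by_anchor_width(self):
        anchor = np.array([[0.0, 0.0, 10.0, 10.0]])
        out = decode_boxes(anchor, np.array([[1.0, 0.0, 0.0, 0.0]]))
        assert np.allclose(out, [[10.0, 0.0, 20.0, 10.0]])

    def test_tw_log2_doubles_width(self):
        anchor = np.array([[0.0, 0.0, 10.0, 10.0]])
        out = decode_boxes(anchor, np.array([[0.0, 0.0, np.log(2.0), 0.0]]))
        assert out[0, 2] - out[0, 0] == pytest.approx(20.0)

    def test_encode_decode_roundtrip(self):
        rng = np.random.default_rng(0)
        anchors = np.concatenate([rng.uniform(0, 40, (50, 2)), rng.uniform(45, 90, (50, 2))], axis=1)
        boxes = np.concatenate([rng.uniform(0, 40, (50, 2)), rng.uniform(45, 90, (50, 2))], axis=1)
        assert np.allclose(decode_boxes(anchors, encode_boxes(anchors, boxes)), boxes)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            decode_boxes(np.array([[0, 0, 1, 1]]), np.array([[np.nan, 0, 0, 0]]))


class TestFilterProposals:
    def test_clipping_worked_example(self):
        boxes, scores = filter_proposals(
            np.array([[-5.0, -5.0, 10.0, 10.0]]), np.array([0.9]), (64, 64),
            ProposalConfig(min_size=1),
        )
        assert np.allclose(boxes, [[0.0, 0.0, 10.0, 10.0]])

    def test_min_size_removes_small_boxes(self):
        boxes = np.array([[0.0, 0.0, 10.0, 30.0], [0.0, 0.0, 30.0, 30.0]])
        out, _ = filter_proposals(boxes, np.array([0.9, 0.1]), (64, 64), ProposalConfig(min_size=16))
        assert len(out) == 1 and np.allclose(out[0], [0, 0, 30, 30])

    def test_sort_and_topn(self):
        rng = np.random.default_rng(1)
        boxes = np.tile(np.array([[0.0, 0.0, 20.0, 20.0]]), (10_000, 1))
        scores = rng.random(10_000)
        out, s = filter_proposals(boxes, scores, (64, 64), ProposalConfig(pre_nms_topN=6000, min_size=8))
        assert len(out) == 6000
        assert np.all(np.diff(s) <= 0)

    def test_stable_tie_break(self):
        boxes = np.array([[0.0, 0.0, float(10 + i), 20.0] for i in range(4)])
        _, s = filter_proposals(boxes, np.array([0.5, 0.5, 0.9, 0.5]), (64, 64), ProposalConfig(min_size=1))
        assert s[0] == 0.9

    def test_empty_input(self):
        out, s = filter_proposals(np.zeros((0, 4)), np.zeros(0), (64, 64))
        assert len(out) == 0 and len(s) == 0


class TestNms:
    def test_single_box_kept(self):
        assert list(nms(np.array([[0, 0, 5, 5]]), np.array([0.7]), 0.5)) == [0]

    def test_duplicate_boxes_keep_one(self):
        boxes = np.array([[0.0, 0.0, 5.0, 5.0], [0.0, 0.0, 5.0, 5.0]])
        keep = nms(boxes, np.array([0.5, 0.5]), 0.5)
        assert list(keep) == [0]  # tie -> lower index

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 300))
        xy = rng.uniform(0, 80, (n, 2))
        wh = rng.uniform(5, 30, (n, 2))
        boxes = np.concatenate([xy, xy + wh], axis=1)
        scores = rng.random(n)
        assert list(nms(boxes, scores, 0.5)) == brute_force_nms(boxes, scores, 0.5)

    def test_post_topn_truncates(self):
        boxes = np.array([[0, 0, 5, 5], [20, 20, 25, 25], [40, 40, 45, 45]], dtype=float)
        keep = nms(boxes, np.array([0.9, 0.8, 0.7]), 0.5, post_nms_topN=2)
        assert list(keep) == [0, 1]


class TestRoiPool:
    def test_worked_quadrant_example(self):
        fm = np.arange(1, 17, dtype=float).reshape(4, 4)
        out = roi_pool(fm, np.array([[0.0, 0.0, 4.0, 4.0]]), (2, 2))
        assert np.array_equal(out[0], [[6.0, 8.0], [14.0, 16.0]])

    def test_constant_map_constant_output(self):
        fm = np.full((8, 8), 0.3)
        out = roi_pool(fm, np.array([[0.0, 0.0, 8.0, 8.0]]), (3, 3))
        assert np.allclose(out, 0.3)

    def test_aligned_identity(self):
        fm = np.random.default_rng(2).random((6, 6))
        out = roi_pool(fm, np.array([[1.0, 2.0, 4.0, 5.0]]), (3, 3))
        assert np.array_equal(out[0], fm[2:5, 1:4])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        fm = rng.random((8, 8))
        x0, y0 = rng.uniform(0, 6.5, 2)
        roi = np.array([x0, y0, x0 + rng.uniform(1, 8 - x0), y0 + rng.uniform(1, 8 - y0)])
        out = roi_pool(fm, roi[None, :], (2, 2))
        assert np.allclose(out[0], naive_roi_pool(fm, roi, 2, 2))

    def test_degenerate_roi_yields_zeros(self):
        fm = np.ones((4, 4))
        out = roi_pool(fm, np.array([[2.0, 2.0, 2.0, 2.0]]), (2, 2))
        assert np.array_equal(out[0], np.zeros((2, 2)))


class TestMultitaskLoss:
    def test_perfect_predictions_zero_loss(self):
        cls = np.array([[0.0, 1.0], [1.0, 0.0]])
        tgt = np.array([1, 0])
        loss = multitask_loss(cls, tgt, np.zeros((2, 4)), np.zeros((2, 4)), np.array([True, False]))
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_half_probability_gives_ln2(self):
        cls = np.array([[0.5, 0.5]])
        loss = multitask_loss(cls, np.array([1]), np.zeros((1, 4)), np.zeros((1, 4)), np.array([True]))
        assert loss == pytest.approx(np.log(2.0))

    def test_smooth_l1_quadratic_branch(self):
        cls = np.array([[0.0, 1.0]])
        preds = np.full((1, 4), 0.5)
        loss = multitask_loss(cls, np.array([1]), preds, np.zeros((1, 4)), np.array([True]))
        assert loss == pytest.approx(4 * 0.125)

    def test_no_positives_drops_localization(self):
        cls = np.array([[0.0, 1.0]])
        loss = multitask_loss(cls, np.array([1]), np.full((1, 4), 99.0), np.zeros((1, 4)), np.array([False]))
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_no_samples_raises(self):
        with pytest.raises(ValueError):
            multitask_loss(np.zeros((0, 2)), np.zeros(0), np.zeros((0, 4)), np.zeros((0, 4)), np.zeros(0, bool))


class TestTraining:
    def test_overfit_single_scene(self, detector_scenes):
        model = RBCDetector(n_steps_rpn=200, n_steps_roi=100, random_state=0).fit(detector_scenes[:1])
        losses = model.loss_history_["rpn"]
        assert losses[-1] <= 0.1 * losses[0]

    def test_fixed_seed_reproduces_loss_trajectory(self, detector_scenes):
        kw = dict(n_steps_rpn=40, n_steps_roi=40, random_state=5)
        m1 = RBCDetector(**kw).fit(detector_scenes[:4])
        m2 = RBCDetector(**kw).fit(detector_scenes[:4])
        assert m1.loss_history_ == m2.loss_history_

    def test_no_positive_anchors_diagnostic(self, detector_scenes):
        with pytest.raises(ValueError, match="positive anchors"):
            RBCDetector(scales=(200.0,), n_steps_rpn=10, n_steps_roi=10).fit(detector_scenes[:2])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            RBCDetector().fit([])

    def test_train_detector_wrapper_config(self, detector_scenes):
        model = train_detector(detector_scenes[:2], {"n_steps_rpn": 20, "n_steps_roi": 20}, seed=1)
        assert model.n_steps_rpn == 20 and hasattr(model, "roi_cls_w_")


class TestInference:
    def test_detection_is_deterministic(self, trained_detector, detector_scenes):
        img = detector_scenes[0].image
        d1 = trained_detector.predict(img)
        d2 = trained_detector.predict(img)
        assert [d.box for d in d1] == [d.box for d in d2]
        assert [d.score for d in d1] == [d.score for d in d2]

    def test_blank_image_has_no_detections(self, trained_detector):
        blank = np.full((64, 64), 0.85)
        assert trained_detector.predict(blank) == []

    def test_single_cell_recovered(self, trained_detector, single_cell_scene):
        dets = trained_detector.predict(single_cell_scene.image)
        assert len(dets) == 1
        iou = box_iou_matrix(np.array([dets[0].box]), np.array([single_cell_scene.boxes[0].box]))
        assert iou[0, 0] >= 0.5

    def test_tiny_image_rejected(self, trained_detector):
        with pytest.raises(ValueError, match="stride"):
            trained_detector.predict(np.zeros((4, 4)))

    def test_save_load_roundtrip(self, trained_detector, single_cell_scene, tmp_path):
        path = str(tmp_path / "model.npz")
        trained_detector.save(path)
        loaded = RBCDetector.load(path)
        d1 = trained_detector.predict(single_cell_scene.image)
        d2 = loaded.predict(single_cell_scene.image)
        assert [d.box for d in d1] == [d.box for d in d2]


class TestLabeling:
    def test_empty_detections_zero_mask(self):
        assert not label_cells((8, 8), []).any()

    def test_single_box_pixel_count(self):
        mask = label_cells((8, 8), [Detection(box=(2.0, 2.0, 5.0, 5.0))])
        assert mask.sum() == 9
        assert mask[2:5, 2:5].all()

    def test_overlapping_boxes_union(self):
        dets = [Detection(box=(0.0, 0.0, 4.0, 4.0)), Detection(box=(2.0, 2.0, 6.0, 6.0))]
        mask = label_cells((8, 8), dets)
        assert set(np.unique(mask)) <= {0, 1}
        assert mask.sum() == 16 + 16 - 4

    def test_score_and_area_filters(self):
        dets = [
            Detection(box=(0.0, 0.0, 10.0, 10.0), score=0.9),
            Detection(box=(20.0, 20.0, 30.0, 30.0), score=0.2),   # low score
            Detection(box=(40.0, 40.0, 41.0, 41.0), score=0.9),   # tiny area
        ]
        kept = filter_detections(dets, DetectionFilterConfig(score_threshold=0.5))
        assert [d.box for d in kept] == [dets[0].box]

    def test_rgi_filter_removes_background_box(self, single_cell_scene):
        scene = single_cell_scene
        true_det = Detection(box=scene.boxes[0].box, score=0.9)
        # put the decoy in the empty corner farthest from the cell
        cx, cy = true_det.center
        corners = [(13.0, 13.0), (13.0, 51.0), (51.0, 13.0), (51.0, 51.0)]
        bx, by = max(corners, key=lambda c: (c[0] - cx) ** 2 + (c[1] - cy) ** 2)
        bg_det = Detection(box=(bx - 7, by - 7, bx + 7, by + 7), score=0.9)
        cfg = DetectionFilterConfig(score_threshold=0.5, rgi_threshold=0.3, area_range=(0.1, 10.0))
        kept = filter_detections([true_det, bg_det], cfg, image=scene.image)
        assert [d.box for d in kept] == [true_det.box]
        mask = label_cells(scene.image.shape, [true_det, bg_det], cfg, image=scene.image)
        x0, y0, x1, y1 = (int(v) for v in true_det.box)
        assert mask.sum() == (x1 - x0) * (y1 - y0)
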