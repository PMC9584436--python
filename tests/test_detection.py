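"""Anchor generation, multi-field crops, box corrections, NMS, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cender.core import AnchorBox, Correction, Region2D, box_iou
from cender.detection import (
    DetectionConfig,
    apply_correction,
    correction_targets,
    crop_multifield,
    evaluate_detection,
    find_local_maxima,
    make_anchors,
    nms,
)


class TestLocalMaxima:
    def test_two_isolated_bright_pixels(self):
        img = np.zeros((20, 20))
        img[5, 5] = 10.0
        img[15, 12] = 8.0
        peaks = find_local_maxima(img, floor=1.0)
        assert sorted(map(tuple, peaks)) == [(5, 5), (12, 15)]

    def test_constant_image_no_peaks(self):
        assert len(find_local_maxima(np.full((10, 10), 3.0), floor=4.0)) == 0

    def test_row_major_order(self):
        img = np.zeros((10, 10))
        img[2, 7] = img[6, 1] = 5.0
        peaks = find_local_maxima(img, floor=1.0)
        assert [tuple(p) for p in peaks] == [(7, 2), (1, 6)]

    def test_synthetic_blob_centers_have_nearby_peaks(self, dataset, preprocessed):
        vol, gt = dataset[0]
        _mip, head, _frame = preprocessed[0]
        hits = total = 0
        for z in range(vol.red.shape[0]):
            peaks = find_local_maxima(vol.red[z], head.head_mask)
            for g in gt.regions:
                if g.z != z:
                    continue
                total += 1
                cx, cy = g.center
                if len(peaks) and np.min(np.hypot(peaks[:, 0] - cx, peaks[:, 1] - cy)) <= 3:
                    hits += 1
        assert hits / total >= 0.90


class TestAnchors:
    def test_center_arithmetic(self):
        (a,) = make_anchors(np.array([[10, 10]]), [9], (64, 64))
        assert (a.x, a.y, a.w, a.h) == (6.0, 6.0, 9.0, 9.0)
        assert a.center == (10.5, 10.5)
        assert not a.clipped

    def test_cardinality(self):
        anchors = make_anchors(np.array([[10, 10], [20, 20], [30, 30]]), [7, 11], (64, 64))
        assert len(anchors) == 6

    def test_corner_anchor_clipped_but_retained(self):
        (a,) = make_anchors(np.array([[1, 1]]), [9], (64, 64))
        assert a.clipped
        assert a.w == 9.0


class TestMultifield:
    CFG = DetectionConfig()

    def test_concentric_center_value(self):
        img = np.zeros((100, 100), dtype=np.float32)
        img[50, 50] = 7.0
        a = make_anchors(np.array([[50, 50]]), [9], img.shape)[0]
        patch = crop_multifield(img, a, self.CFG, scale=7.0)
        for ch in range(4):  # all un-resized channels
            assert patch[ch, 20, 20] == 1.0

    def test_all_zero_frame(self):
        a = make_anchors(np.array([[50, 50]]), [9], (100, 100))[0]
        assert crop_multifield(np.zeros((100, 100)), a, self.CFG).sum() == 0

    def test_off_edge_padding_is_zero(self):
        img = np.ones((100, 100), dtype=np.float32)
        a = make_anchors(np.array([[2, 50]]), [9], img.shape)[0]
        patch = crop_multifield(img, a, self.CFG, scale=1.0)
        ch41 = patch[3]  # the 41x41 field, un-resized
        assert np.all(ch41[:, :18] == 0)  # columns left of the image edge
        assert np.all(ch41[:, 19:] == 1)

    def test_shape_and_range(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (60, 60)).astype(np.float32)
        a = make_anchors(np.array([[30, 30]]), [9], img.shape)[0]
        patch = crop_multifield(img, a, self.CFG)
        assert patch.shape == (5, 41, 41)
        assert patch.min() >= 0.0 and patch.max() <= 1.0


class TestCorrections:
    def test_identity(self):
        a = AnchorBox(10, 10, 9, 9, 0)
        c = correction_targets(a, Region2D(10, 10, 9, 9, 0))
        assert (c.dx, c.dy, c.omega, c.eta) == (0.0, 0.0, 1.0, 1.0)
        r = apply_correction(a, c)
        assert (r.x, r.y, r.w, r.h) == (10.0, 10.0, 9.0, 9.0)

    def test_worked_example(self):
        a = AnchorBox(10, 10, 9, 9, 0)
        c = correction_targets(a, Region2D(12, 11, 7, 10, 0))
        assert np.allclose([c.dx, c.dy, c.omega, c.eta], [2 / 9, 1 / 9, 7 / 9, 10 / 9])

    def test_forward_example(self):
        r = apply_correction(AnchorBox(0, 0, 10, 10, 3), Correction(0.5, 0.5, 0.5, 0.5))
        assert (r.x, r.y, r.w, r.h, r.z) == (5.0, 5.0, 5.0, 5.0, 3)

    @settings(max_examples=200, deadline=None)
    @given(
        ax=st.integers(-20, 200), ay=st.integers(-20, 200),
        aw=st.integers(1, 40), ah=st.integers(1, 40),
        gx=st.integers(-20, 200), gy=st.integers(-20, 200),
        gw=st.integers(1, 40), gh=st.integers(1, 40),
    )
    def test_round_trip_exact(self, ax, ay, aw, ah, gx, gy, gw, gh):
        a = AnchorBox(ax, ay, aw, ah, 0)
        g = Region2D(gx, gy, gw, gh, 0)
        r = apply_correction(a, correction_targets(a, g))
        assert abs(r.x - g.x) < 1e-9 and abs(r.y - g.y) < 1e-9
        assert abs(r.w - g.w) < 1e-9 and abs(r.h - g.h) < 1e-9

    def test_non_positive_scale_rejected(self):
        with pytest.raises(ValueError):
            Correction(0, 0, 0.0, 1.0)


class TestNms:
    def test_single_region_unchanged(self):
        r = Region2D(0, 0, 5, 5, 0, score=0.9)
        assert nms([r]) == [r]

    def test_duplicate_keeps_higher_score(self):
        a = Region2D(0, 0, 5, 5, 0, score=0.9)
        b = Region2D(0, 0, 5, 5, 0, score=0.8)
        assert nms([a, b]) == [a]

    def test_greedy_chain(self):
        # A overlaps B, B overlaps C, A and C disjoint -> {A, C}
        a = Region2D(0, 0, 6, 6, 0, score=0.9)
        b = Region2D(3, 0, 6, 6, 0, score=0.8)
        c = Region2D(6, 0, 6, 6, 0, score=0.7)
        assert box_iou((a.x, a.y, a.w, a.h), (c.x, c.y, c.w, c.h)) == 0.0
        kept = nms([a, b, c], overlap_threshold=0.2)
        assert kept == [a, c]

    def test_score_floor_applied(self):
        assert nms([Region2D(0, 0, 5, 5, 0, score=0.3)]) == []

    def test_output_overlap_free_subset(self):
        rng = np.random.default_rng(3)
        regions = [
            Region2D(rng.integers(0, 30), rng.integers(0, 30), 8, 8, 0,
                     score=float(rng.uniform(0.4, 1)))
            for _ in range(40)
        ]
        kept = nms(regions)
        assert all(k in regions for k in kept)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert box_iou((a.x, a.y, a.w, a.h), (b.x, b.y, b.w, b.h)) <= 0.20


class TestEvaluateDetection:
    def test_perfect(self):
        gt = [Region2D(0, 0, 5, 5, 0), Region2D(10, 10, 5, 5, 1)]
        assert evaluate_detection(gt, gt) == (1.0, 1.0, 1.0)

    def test_no_overlap(self):
        pred = [Region2D(50, 50, 5, 5, 0)]
        gt = [Region2D(0, 0, 5, 5, 0)]
        assert evaluate_detection(pred, gt) == (0.0, 0.0, 0.0)

    def test_half_recall_harmonic_mean(self):
        gt = [Region2D(0, 0, 5, 5, 0), Region2D(20, 20, 5, 5, 0)]
        p, r, f = evaluate_detection([gt[0]], gt)
        assert (p, r) == (1.0, 0.5)
        assert np.isclose(f, 2 / 3)

    def test_same_frame_required(self):
        pred = [Region2D(0, 0, 5, 5, 1)]
        gt = [Region2D(0, 0, 5, 5, 0)]
        assert evaluate_detection(pred, gt)[0] == 0.0

    def test_empty_gt_rejected(self):
        with pytest.raises(ValueError):
            evaluate_detection([], [])

    def test_matches_exhaustive_matching_on_small_instances(self):
        """Greedy one-to-one matching agrees with the exhaustive bipartite
        optimum (max #TP) on instances with <= 8 regions."""
        from itertools import permutations

        rng = np.random.default_rng(11)
        for _ in range(30):
            pred = [
                Region2D(rng.integers(0, 20), rng.integers(0, 20), 6, 6, 0)
                for _ in range(rng.integers(1, 5))
            ]
            gt = [
                Region2D(rng.integers(0, 20), rng.integers(0, 20), 6, 6, 0)
                for _ in range(rng.integers(1, 5))
            ]
            _p, _r, _f = evaluate_detection(pred, gt, 0.3)
            tp_greedy = round(_p * len(pred))
            iou_m = np.array([
                [box_iou((p.x, p.y, p.w, p.h), (g.x, g.y, g.w, g.h)) for g in gt]
                for p in pred
            ])
            best = 0
            if len(pred) <= len(gt):
                for perm in permutations(range(len(gt)), len(pred)):
                    best = max(best, sum(iou_m[i, j] > 0.3 for i, j in enumerate(perm)))
            else:
                for perm in permutations(range(len(pred)), len(gt)):
                    best = max(best, sum(iou_m[i, j] > 0.3 for j, i in enumerate(perm)))
            assert tp_greedy == best
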