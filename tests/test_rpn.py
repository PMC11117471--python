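"""Proposal geometry: IoU, anchor grids, labelling, offset coding, NMS."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lungrpn.anchors import AnchorSet, BoxWH
from lungrpn.rpn import (
    IGNORE,
    NEGATIVE,
    POSITIVE,
    Box,
    RPNConfig,
    ScoredBox,
    decode_offsets,
    encode_offsets,
    generate_anchor_grid,
    iou,
    iou_matrix,
    label_anchors,
    nms,
    select_proposals,
)

boxes_strategy = st.builds(
    lambda x, y, w, h: Box(x, y, x + w, y + h),
    st.floats(-50, 50),
    st.floats(-50, 50),
    st.floats(0.5, 40),
    st.floats(0.5, 40),
)


class TestIoU:
    def test_identical_boxes(self):
        b = Box(2, 3, 10, 12)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(Box(0, 0, 2, 2), Box(5, 5, 7, 7)) == 0.0

    def test_hand_case_one_seventh(self):
        assert iou(Box(0, 0, 2, 2), Box(1, 1, 3, 3)) == pytest.approx(1 / 7)

    @given(boxes_strategy, boxes_strategy)
    def test_symmetry_and_range(self, a, b):
        assert iou(a, b) == pytest.approx(iou(b, a))
        assert 0.0 <= iou(a, b) <= 1.0

    @given(boxes_strategy, boxes_strategy, st.floats(-20, 20), st.floats(-20, 20))
    def test_translation_invariance(self, a, b, dx, dy):
        shift = lambda bx: Box(bx.x_min + dx, bx.y_min + dy, bx.x_max + dx, bx.y_max + dy)
        assert iou(shift(a), shift(b)) == pytest.approx(iou(a, b), abs=1e-9)

    def test_matrix_agrees_with_scalar(self, rng):
        A = [Box(*sorted(rng.uniform(0, 20, 2)), *(30 + np.arange(2.0))) for _ in range(5)]
        B = [Box(x, x, x + 6, x + 9) for x in range(4)]
        m = iou_matrix(A, B)
        for i, a in enumerate(A):
            for j, b in enumerate(B):
                assert m[i, j] == pytest.approx(iou(a, b))

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            Box(3, 3, 3, 5)


class TestAnchorGrid:
    def test_single_cell_single_anchor_centred(self):
        (box,) = generate_anchor_grid((1, 1), 16, [(8.0, 6.0)])
        assert box.center == (8.0, 8.0)
        assert (box.width, box.height) == (8.0, 6.0)

    def test_count_is_cells_times_shapes(self):
        shapes = [(4.0, 4.0)] * 5
        assert len(generate_anchor_grid((4, 4), 8, shapes)) == 80

    def test_grid_shift_translates_by_stride(self):
        shapes = AnchorSet(shapes=(BoxWH(6.0, 6.0),))
        grid = generate_anchor_grid((2, 3), 10, shapes)
        # cell (0, 1) box = cell (0, 0) box shifted by one stride in x
        assert grid[1].x_min == grid[0].x_min + 10
        assert grid[1].y_min == grid[0].y_min

    def test_empty_anchor_set_rejected(self):
        with pytest.raises(ValueError):
            generate_anchor_grid((2, 2), 8, [])


class TestLabelAnchors:
    CFG = RPNConfig(pos_iou=0.7, neg_iou=0.3)

    def test_anchor_identical_to_gt_is_positive(self):
        gt = Box(10, 10, 20, 20)
        anchors = [gt, Box(100, 100, 110, 110)]
        labels = label_anchors(anchors, [gt], self.CFG)
        assert labels[0] == POSITIVE and labels[1] == NEGATIVE

    def test_empty_gt_all_negative(self):
        anchors = [Box(0, 0, 4, 4), Box(8, 8, 12, 12)]
        assert np.all(label_anchors(anchors, [], self.CFG) == NEGATIVE)

    def test_argmax_rule_rescues_low_iou_best_anchor(self):
        gt = Box(0, 0, 4, 4)
        best = Box(0, 0, 10, 10)  # IoU = 16/100 = 0.16 < pos_iou
        far = Box(30, 30, 40, 40)  # IoU = 0
        assert iou(best, gt) == pytest.approx(0.16)
        labels = label_anchors([best, far], [gt], self.CFG)
        assert labels[0] == POSITIVE and labels[1] == NEGATIVE

    def test_intermediate_overlap_is_ignored(self):
        gt = Box(0, 0, 10, 10)
        mid = Box(0, 4, 10, 14)  # IoU = 60/140 ~ 0.43, between neg and pos
        other = Box(0, 0, 10, 10)  # the argmax anchor
        labels = label_anchors([other, mid], [gt], self.CFG)
        assert labels[1] == IGNORE


class TestOffsets:
    def test_gt_equals_anchor_gives_zero(self):
        b = Box(3, 4, 13, 24)
        np.testing.assert_allclose(encode_offsets(b, b), 0.0, atol=1e-12)

    def test_hand_case_pure_translation(self):
        off = encode_offsets(Box(5, 5, 15, 15), Box(0, 0, 10, 10))
        np.testing.assert_allclose(off, [0.5, 0.5, 0.0, 0.0])

    def test_zero_offsets_decode_to_anchor(self):
        a = Box(2, 2, 9, 11)
        assert decode_offsets([0, 0, 0, 0], a) == a

    @given(boxes_strategy, boxes_strategy)
    def test_roundtrip_identity(self, gt, anchor):
        dec = decode_offsets(encode_offsets(gt, anchor), anchor)
        np.testing.assert_allclose(dec.as_array(), gt.as_array(), atol=1e-9)


class TestNMS:
    def test_single_box_kept(self):
        sb = ScoredBox(Box(0, 0, 5, 5), 0.9)
        assert nms([sb], 0.5) == [sb]

    def test_overlapping_pair_keeps_higher_score(self):
        hi = ScoredBox(Box(0, 0, 10, 10), 0.9)
        lo = ScoredBox(Box(0, 1, 10, 11), 0.5)  # IoU = 90/110 ~ 0.82
        assert iou(hi.box, lo.box) > 0.7
        assert nms([lo, hi], 0.7) == [hi]

    def test_disjoint_boxes_all_kept_in_score_order(self):
        boxes = [
            ScoredBox(Box(0, 0, 4, 4), 0.2),
            ScoredBox(Box(10, 10, 14, 14), 0.8),
            ScoredBox(Box(20, 20, 24, 24), 0.5),
        ]
        assert [b.score for b in nms(boxes, 0.5)] == [0.8, 0.5, 0.2]

    def test_order_independence(self, rng):
        boxes = [
            ScoredBox(
                Box(x, y, x + w, y + h), float(s)
            )
            for x, y, w, h, s in zip(
                rng.uniform(0, 40, 30),
                rng.uniform(0, 40, 30),
                rng.uniform(2, 15, 30),
                rng.uniform(2, 15, 30),
                rng.uniform(0, 1, 30),
            )
        ]
        ref = nms(boxes, 0.4)
        for _ in range(5):
            perm = [boxes[i] for i in rng.permutation(len(boxes))]
            assert nms(perm, 0.4) == ref

    def test_survivors_pairwise_below_threshold(self, rng):
        boxes = [
            ScoredBox(Box(x, x, x + 8, x + 8), float(s))
            for x, s in zip(rng.uniform(0, 30, 40), rng.uniform(0, 1, 40))
        ]
        kept = nms(boxes, 0.3)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert iou(a.box, b.box) < 0.3


class TestSelectProposals:
    def test_fewer_than_top_n_all_returned(self):
        boxes = [ScoredBox(Box(i * 20, 0, i * 20 + 5, 5), 0.5) for i in range(3)]
        assert len(select_proposals(boxes, RPNConfig(top_n=300))) == 3

    def test_top_one_keeps_best_survivor(self):
        boxes = [
            ScoredBox(Box(0, 0, 5, 5), 0.4),
            ScoredBox(Box(20, 20, 25, 25), 0.9),
        ]
        (winner,) = select_proposals(boxes, RPNConfig(top_n=1))
        assert winner.score == 0.9

    def test_output_never_exceeds_top_n(self, rng):
        boxes = [
            ScoredBox(Box(x, x, x + 4, x + 4), float(s))
            for x, s in zip(rng.uniform(0, 200, 100), rng.uniform(0, 1, 100))
        ]
        assert len(select_proposals(boxes, RPNConfig(top_n=7))) <= 7

    def test_invalid_threshold_order_rejected(self):
        with pytest.raises(ValueError):
            RPNConfig(pos_iou=0.3, neg_iou=0.5)
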