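"""Log-IoU and partitioned losses, Smooth-L1, P_Box, head terms, ledger."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromoseg import (
    EmptyMaskError,
    aggregate_losses,
    head_supervision_losses,
    iou_loss,
    k_iou_loss,
    mask_iou,
    p_box,
    partition_grid,
    smooth_l1,
)
from chromoseg.losses import DEFAULT_EPS, binary_cross_entropy

from conftest import random_mask


def quartered_square():
    """Solid 8x8 gt whose 2x2 partition cells are its four 4x4 quadrants."""
    gt = np.zeros((12, 12), bool)
    gt[2:10, 2:10] = True
    return gt, partition_grid(gt, 2, 2)


class TestIoULoss:
    def test_perfect_prediction_is_zero(self, rng):
        gt = random_mask(rng, nonempty=True)
        assert iou_loss(gt, gt) == 0.0

    def test_half_overlap_is_ln2(self):
        # pred covers half the gt and nothing else: IoU = 1/2
        gt = np.zeros((8, 8), bool)
        gt[0:4, 0:4] = True
        pred = np.zeros((8, 8), bool)
        pred[0:2, 0:4] = True
        assert mask_iou(pred, gt) == 0.5
        assert iou_loss(pred, gt) == pytest.approx(np.log(2))

    def test_disjoint_clamps_finite(self):
        gt = np.zeros((8, 8), bool)
        gt[0, 0] = True
        pred = np.zeros((8, 8), bool)
        pred[7, 7] = True
        assert iou_loss(pred, gt, eps=1e-7) == pytest.approx(-np.log(1e-7))

    def test_empty_gt_raises(self):
        with pytest.raises(EmptyMaskError):
            iou_loss(np.ones((4, 4), bool), np.zeros((4, 4), bool))


class TestKIoULoss:
    def test_single_cell_reduces_to_iou_loss(self, rng):
        for _ in range(20):
            gt = random_mask(rng, nonempty=True)
            pred = random_mask(rng)
            part = partition_grid(gt, 1, 1)
            assert k_iou_loss(pred, gt, part) == iou_loss(pred, gt)

    def test_quarter_fixture_weighted(self):
        # per-cell IoU (0.5, 1, 1, 1) with delta = 0.25 each
        gt, part = quartered_square()
        pred = gt.copy()
        pred[2:6, 2:4] = False  # halve the gt inside cell 0 only
        assert k_iou_loss(pred, gt, part, weighted=True) == pytest.approx(
            0.25 * np.log(2)
        )

    def test_quarter_fixture_unweighted_is_harsher(self):
        gt, part = quartered_square()
        pred = gt.copy()
        pred[2:6, 2:4] = False
        unweighted = k_iou_loss(pred, gt, part, weighted=False)
        weighted = k_iou_loss(pred, gt, part, weighted=True)
        assert unweighted == pytest.approx(np.log(2))
        assert unweighted > weighted
        assert unweighted > iou_loss(pred, gt)

    def test_weighted_never_exceeds_unweighted(self, rng):
        for _ in range(30):
            gt = random_mask(rng, nonempty=True)
            pred = random_mask(rng)
            part = partition_grid(gt, 2, 2)
            assert (
                k_iou_loss(pred, gt, part, weighted=True)
                <= k_iou_loss(pred, gt, part, weighted=False) + 1e-12
            )

    def test_degrading_one_cell_never_decreases_loss(self, rng):
        for _ in range(20):
            gt = random_mask(rng, nonempty=True)
            part = partition_grid(gt, 2, 2)
            pred = gt.copy()
            base = k_iou_loss(pred, gt, part)
            cell = int(np.flatnonzero(part.delta > 0)[0])
            sel = (part.cell_of_pixel == cell) & gt
            rr, cc = np.nonzero(sel)
            pred[rr[0], cc[0]] = False
            assert k_iou_loss(pred, gt, part) >= base

    def test_finite_for_disjoint_masks_fine_grid(self):
        gt = np.zeros((16, 16), bool)
        gt[0:8, 0:8] = True
        pred = np.zeros((16, 16), bool)
        pred[9:16, 9:16] = True
        part = partition_grid(gt, 4, 4)
        for weighted in (True, False):
            v = k_iou_loss(pred, gt, part, weighted=weighted)
            assert np.isfinite(v)

    def test_soft_masks_match_binary_at_extremes(self, rng):
        gt = random_mask(rng, nonempty=True)
        pred = random_mask(rng)
        part = partition_grid(gt, 2, 2)
        hard = k_iou_loss(pred, gt, part)
        soft = k_iou_loss(pred.astype(float) * 0.999999 + 1e-7, gt, part)
        assert soft == pytest.approx(hard, rel=1e-3)


class TestSmoothL1:
    @pytest.mark.parametrize(
        "d, expected",
        [
            (np.zeros(4), 0.0),
            (np.array([0.5, 0, 0, 0]), 0.125 / 4),
            (np.array([2.0, 0, 0, 0]), 1.5 / 4),
        ],
    )
    def test_closed_form(self, d, expected):
        assert smooth_l1(d, np.zeros(4)) == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            smooth_l1(np.array([np.inf, 0, 0, 0]), np.zeros(4))


class TestPBox:
    def test_anchors(self):
        assert p_box(0.0) == 1.0
        assert p_box(0.5) == pytest.approx(1 - np.tanh(0.5))
        assert p_box(50.0) == pytest.approx(0.0, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            p_box(-0.1)

    @given(st.floats(0, 20), st.floats(0, 20))
    @settings(max_examples=100, derandomize=True)
    def test_strictly_decreasing_into_unit_interval(self, a, b):
        va, vb = p_box(a), p_box(b)
        assert 0.0 < va <= 1.0
        if a < b:
            assert va >= vb
            if abs(a - b) > 1e-9 and b < 18:  # tanh saturates in float64
                assert va > vb


class TestHeadSupervision:
    def test_perfect_predictions_vanish(self):
        gt = np.zeros((4, 4), bool)
        gt[1:3, 1:3] = True
        l_cls, l_pbox, l_mask, l_ioumask = head_supervision_losses(
            1.0, 1, 1.0, 1.0, gt.astype(float), gt, 0.8, 0.8
        )
        for v in (l_cls, l_pbox, l_mask, l_ioumask):
            assert v == pytest.approx(0.0, abs=1e-5)

    def test_bce_and_squared_error_closed_forms(self):
        gt = np.ones((2, 2), bool)
        l_cls, _, _, l_ioumask = head_supervision_losses(
            0.5, 1, 1.0, 1.0, gt.astype(float), gt, 0.9, 0.7
        )
        assert l_cls == pytest.approx(np.log(2))
        assert l_ioumask == pytest.approx(0.04)

    def test_mask_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            head_supervision_losses(
                0.5, 1, 0.5, 0.5, np.zeros((2, 2)), np.zeros((3, 3), bool), 0.5, 0.5
            )

    def test_bce_clamp_keeps_finite(self):
        assert np.isfinite(binary_cross_entropy(0.0, 1.0))
        assert np.isfinite(binary_cross_entropy(1.0, 0.0))


class TestAggregate:
    def test_zero_and_unit_ledgers(self):
        assert aggregate_losses(0, 0, 0, 0, 0, 0).total == 0.0
        comp = aggregate_losses(1, 1, 1, 1, 1, 1)
        assert (comp.l_box, comp.l_seg, comp.total) == (3.0, 3.0, 6.0)

    def test_ledger_identities_on_random_components(self, rng):
        for _ in range(20):
            vals = rng.uniform(0, 5, size=6)
            comp = aggregate_losses(*vals)
            assert comp.l_box == pytest.approx(vals[:3].sum(), abs=1e-9)
            assert comp.l_seg == pytest.approx(vals[3:].sum(), abs=1e-9)
            assert comp.total == pytest.approx(vals.sum(), abs=1e-9)

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            aggregate_losses(1, -0.1, 0, 0, 0, 0)
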