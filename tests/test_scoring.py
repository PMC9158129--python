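"""Confidence correction and mask-/box-based NMS."""

import numpy as np
import pytest

from chromoseg import (
    box_iou,
    box_nms,
    correct_confidence,
    correct_detections,
    mask_iou,
    mask_nms,
    omission_scenario,
    pairwise_mask_iou,
)

from conftest import random_detections


def greedy_nms_oracle(scores, ids, overlap, threshold):
    """Exhaustive reference: repeatedly keep the best-scoring survivor."""
    n = len(scores)
    alive = set(range(n))
    kept = []
    while alive:
        best = min(alive, key=lambda i: (-scores[i], ids[i]))
        kept.append(best)
        alive = {
            i for i in alive if i != best and overlap[best][i] <= threshold
        }
    return kept


class TestCorrectConfidence:
    def test_identity_factors(self):
        assert correct_confidence(0.7, 1.0, 1.0) == pytest.approx(0.7)

    def test_default_and_heavy_exponents(self):
        assert correct_confidence(0.9, 0.8, 0.9, alpha=2, beta=1) == pytest.approx(
            0.9 * 0.64 * 0.9
        )
        assert correct_confidence(0.9, 0.8, 0.9, alpha=2, beta=6) == pytest.approx(
            0.9 * 0.64 * 0.9**6
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            correct_confidence(1.2, 0.5, 0.5)
        with pytest.raises(ValueError):
            correct_confidence(0.5, 0.5, 0.5, alpha=-1)

    def test_monotone_in_exponents_and_inputs(self, rng):
        for _ in range(50):
            p, i, b = rng.uniform(0.05, 0.95, size=3)
            assert correct_confidence(p, i, b, 2, 6) <= correct_confidence(p, i, b, 2, 5)
            assert correct_confidence(p, i, b, 3, 6) <= correct_confidence(p, i, b, 2, 6)
            assert correct_confidence(p, i, b, 2, 6) <= correct_confidence(
                p, min(i + 0.01, 1), b, 2, 6
            )

    def test_correct_detections_fills_scores(self, rng):
        dets = random_detections(rng, 5)
        out = correct_detections(dets, 2, 6)
        for d_in, d_out in zip(dets, out):
            assert d_out.score == pytest.approx(
                d_in.p_cls * d_in.iou_mask_pred**2 * d_in.p_box**6
            )
            assert d_out.p_cls == d_in.p_cls  # raw never overwritten


class TestMaskNMS:
    def test_single_detection_kept(self, rng):
        dets = random_detections(rng, 1)
        assert mask_nms(dets, 0.5) == [0]

    def test_omission_scenario_mask_keeps_both(self):
        det_a, det_b = omission_scenario()
        assert 0.7 <= box_iou(det_a.box, det_b.box) <= 0.9
        assert 0.1 <= mask_iou(det_a.mask, det_b.mask) <= 0.3
        assert mask_nms([det_a, det_b], 0.5) == [0, 1]
        assert box_nms([det_a, det_b], 0.5) == [0]

    def test_matches_oracle_with_ties(self, rng):
        for _ in range(50):
            dets = random_detections(rng, 12, tie_scores=True)
            overlap = pairwise_mask_iou([d.mask for d in dets])
            np.fill_diagonal(overlap, 0.0)
            expect = greedy_nms_oracle(
                [d.score for d in dets], [d.instance_id for d in dets],
                overlap, 0.3,
            )
            assert mask_nms(dets, 0.3) == expect

    def test_permutation_invariant_kept_set(self, rng):
        dets = random_detections(rng, 10, tie_scores=True)
        kept = mask_nms(dets, 0.4)
        perm = rng.permutation(len(dets))
        shuffled = [dets[i] for i in perm]
        kept_ids = {dets[i].instance_id for i in kept}
        kept_ids_shuffled = {shuffled[i].instance_id for i in mask_nms(shuffled, 0.4)}
        assert kept_ids == kept_ids_shuffled

    def test_threshold_extremes(self, rng):
        dets = random_detections(rng, 8)
        overlap = pairwise_mask_iou([d.mask for d in dets])
        np.fill_diagonal(overlap, 0.0)
        assert mask_nms(dets, 1.0) == sorted(
            range(8), key=lambda i: (-dets[i].score, i)
        )
        # threshold 0: kept detections are pairwise fully non-overlapping
        kept = mask_nms(dets, 0.0)
        for a in kept:
            for b in kept:
                if a != b:
                    assert overlap[a, b] == 0.0

    def test_kept_pairwise_below_threshold(self, rng):
        dets = random_detections(rng, 15)
        kept = mask_nms(dets, 0.35)
        overlap = pairwise_mask_iou([d.mask for d in dets])
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert overlap[a, b] <= 0.35

    def test_mixed_grids_rejected(self, rng):
        d1 = random_detections(rng, 1, shape=(16, 16))[0]
        d2 = random_detections(rng, 1, shape=(24, 24))[0]
        with pytest.raises(ValueError, match="grid"):
            mask_nms([d1, d2], 0.5)

    def test_raw_score_key_orders_by_p_cls(self, rng):
        dets = random_detections(rng, 6)
        kept = mask_nms(dets, 1.0, score_key="raw")
        assert kept == sorted(range(6), key=lambda i: (-dets[i].p_cls, i))


class TestBoxNMS:
    def test_disjoint_boxes_all_kept(self, rng):
        dets = random_detections(rng, 4, shape=(8, 8))
        # rebuild with disjoint boxes via disjoint masks
        from chromoseg import Detection, mask_to_box

        out = []
        for i in range(4):
            m = np.zeros((20, 20), bool)
            m[5 * i: 5 * i + 3, 5 * i: 5 * i + 3] = True
            out.append(
                Detection(box=mask_to_box(m), mask=m, p_cls=0.5, p_box=0.5,
                          iou_mask_pred=0.5, instance_id=i, score=0.5)
            )
        assert sorted(box_nms(out, 0.5)) == [0, 1, 2, 3]

    def test_high_overlap_pair_suppressed(self):
        det_a, det_b = omission_scenario()
        assert box_nms([det_a, det_b], 0.5) == [0]
        # strict comparator: at threshold equal to the IoU both survive
        thr = box_iou(det_a.box, det_b.box)
        assert box_nms([det_a, det_b], thr) == [0, 1]

    def test_matches_oracle(self, rng):
        for _ in range(50):
            dets = random_detections(rng, 12, tie_scores=True)
            n = len(dets)
            overlap = np.zeros((n, n))
            for i in range(n):
                for j in range(n):
                    if i != j:
                        overlap[i, j] = box_iou(dets[i].box, dets[j].box)
            expect = greedy_nms_oracle(
                [d.score for d in dets], [d.instance_id for d in dets],
                overlap, 0.3,
            )
            assert box_nms(dets, 0.3) == expect

    def test_mask_nms_keeps_at_least_as_many_when_masks_overlap_less(self, rng):
        # in the elongated regime every pair has mask IoU <= box IoU
        from chromoseg import NoiseConfig, SceneConfig, generate_scene, simulate_detections

        scene = simulate_detections(
            generate_scene(SceneConfig(seed=7, overlap_level=0.6, n_instances=6)),
            NoiseConfig(seed=8),
        )
        dets = correct_detections(scene.detections)
        overlap_ok = all(
            mask_iou(a.mask, b.mask) <= box_iou(a.box, b.box) + 1e-9
            for i, a in enumerate(dets)
            for b in dets[i + 1:]
        )
        if overlap_ok:
            for thr in (0.2, 0.5):
                assert len(mask_nms(dets, thr)) >= len(box_nms(dets, thr))
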