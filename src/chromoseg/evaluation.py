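"""COCO-style mask average precision for single-category instance segmentation.

AP^M is the mean of the average precision at the ten mask-IoU thresholds
0.50, 0.55, ..., 0.95; AP50 and AP75 fix the threshold at 0.50 and 0.75.
The conventions are COCO's: detections are matched to ground truth greedily
in descending score order, each ground-truth mask is matched at most once, a
match requires mask IoU >= threshold (inclusive), and AP is the 101-point
interpolated area under the precision-recall curve.  There is a single
category and no cap on detections per image (scenes here hold tens of
instances, not thousands).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import as_mask, mask_iou
from .scoring import Detection, ScoreKey, _score_of

__all__ = [
    "IOU_THRESHOLDS",
    "EvalResult",
    "match_detections",
    "average_precision",
    "ap_m",
    "evaluate_scenes",
]

IOU_THRESHOLDS = np.arange(0.50, 1.00, 0.05).round(2)
_RECALL_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class EvalResult:
    """AP at each mask-IoU threshold plus the usual summaries.

    ``pr_curves`` maps each threshold to its ``(recall, precision)`` point
    arrays, one point per detection in score order.
    """

    ap_per_threshold: np.ndarray
    ap_m: float
    ap50: float
    ap75: float
    pr_curves: dict[float, tuple[np.ndarray, np.ndarray]]

    def as_dict(self) -> dict[str, float | list[float]]:
        return {
            "ap_m": self.ap_m,
            "ap50": self.ap50,
            "ap75": self.ap75,
            "ap_per_threshold": [float(v) for v in self.ap_per_threshold],
        }


def _sorted_indices(dets: Sequence[Detection], score_key: ScoreKey) -> list[int]:
    return sorted(
        range(len(dets)),
        key=lambda i: (-_score_of(dets[i], score_key), dets[i].instance_id),
    )


def match_detections(
    dets: Sequence[Detection],
    gts: Sequence[np.ndarray],
    iou_threshold: float,
    score_key: ScoreKey = "corrected",
) -> np.ndarray:
    """Label each detection TP/FP by greedy matching in score order.

    A detection is a true positive iff its best-IoU still-unmatched ground
    truth reaches ``iou_threshold``; that ground truth is then consumed.
    Returns a boolean array aligned with the *input* order of ``dets``.
    """
    gts = [as_mask(g) for g in gts]
    shapes = {g.shape for g in gts} | {d.mask.shape for d in dets}
    if len(shapes) > 1:
        raise ValueError(f"masks on mixed grids: {sorted(shapes)}")
    labels = np.zeros(len(dets), dtype=bool)
    matched = np.zeros(len(gts), dtype=bool)
    for i in _sorted_indices(dets, score_key):
        best_iou, best_j = 0.0, -1
        for j, g in enumerate(gts):
            if matched[j]:
                continue
            iou = mask_iou(dets[i].mask, g)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_threshold:
            labels[i] = True
            matched[best_j] = True
    return labels


def _pr_points(
    tp: np.ndarray, scores: np.ndarray, tiebreak: np.ndarray, n_gt: int
) -> tuple[np.ndarray, np.ndarray]:
    order = np.lexsort((tiebreak, -scores))
    tp_sorted = tp[order]
    cum_tp = np.cumsum(tp_sorted)
    cum_fp = np.cumsum(~tp_sorted)
    precision = cum_tp / (cum_tp + cum_fp)
    recall = cum_tp / n_gt if n_gt > 0 else np.zeros_like(cum_tp, dtype=float)
    return recall.astype(float), precision.astype(float)


def average_precision(
    tp: np.ndarray,
    scores: np.ndarray,
    n_gt: int,
    tiebreak: np.ndarray | None = None,
) -> float:
    """101-point interpolated AP from TP/FP labels and scores.

    The precision envelope (running maximum from the right) is sampled at
    recalls 0, 0.01, ..., 1 and averaged.  With no ground truth the AP is
    defined as 0.
    """
    if n_gt < 0:
        raise ValueError("n_gt must be >= 0")
    tp = np.asarray(tp, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if tp.shape != scores.shape:
        raise ValueError("tp and scores must have equal length")
    if n_gt == 0 or tp.size == 0:
        return 0.0
    if tiebreak is None:
        tiebreak = np.arange(tp.size)
    recall, precision = _pr_points(tp, scores, np.asarray(tiebreak), n_gt)
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    # precision at each recall grid point: first PR point with recall >= r
    idx = np.searchsorted(recall, _RECALL_GRID, side="left")
    sampled = np.where(idx < envelope.size, envelope[np.minimum(idx, envelope.size - 1)], 0.0)
    return float(sampled.mean())


def evaluate_scenes(
    scenes: Sequence[tuple[Sequence[Detection], Sequence[np.ndarray]]],
    score_key: ScoreKey = "corrected",
) -> EvalResult:
    """AP^M over a collection of (detections, ground-truth masks) scenes.

    Matching is per scene; TP labels and scores are pooled across scenes for
    each threshold's precision-recall curve, as COCO pools across images.
    """
    n_gt = sum(len(gts) for _, gts in scenes)
    aps = np.zeros(len(IOU_THRESHOLDS))
    pr_curves: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for k, thr in enumerate(IOU_THRESHOLDS):
        tp_all: list[np.ndarray] = []
        score_all: list[np.ndarray] = []
        tiebreak_all: list[np.ndarray] = []
        for scene_idx, (dets, gts) in enumerate(scenes):
            if len(dets) == 0:
                continue
            tp_all.append(match_detections(dets, gts, float(thr), score_key))
            score_all.append(np.array([_score_of(d, score_key) for d in dets]))
            tiebreak_all.append(
                np.array(
                    [scene_idx * 1e6 + d.instance_id for d in dets], dtype=float
                )
            )
        if not tp_all:
            aps[k] = 0.0
            pr_curves[float(thr)] = (np.zeros(0), np.zeros(0))
            continue
        tp = np.concatenate(tp_all)
        scores = np.concatenate(score_all)
        tiebreak = np.concatenate(tiebreak_all)
        aps[k] = average_precision(tp, scores, n_gt, tiebreak)
        pr_curves[float(thr)] = _pr_points(tp, scores, tiebreak, n_gt)
    return EvalResult(
        ap_per_threshold=aps,
        ap_m=float(aps.mean()),
        ap50=float(aps[0]),
        ap75=float(aps[5]),
        pr_curves=pr_curves,
    )


def ap_m(
    dets: Sequence[Detection],
    gts: Sequence[np.ndarray],
    score_key: ScoreKey = "corrected",
) -> EvalResult:
    """Single-scene AP^M; see :func:`evaluate_scenes`."""
    return evaluate_scenes([(dets, gts)], score_key)
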