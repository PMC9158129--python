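"""Confidence correction and non-maximum suppression for instance masks.

Classification confidence alone is a poor ranking signal for overlapping
elongated objects: a proposal can score high on "is this a chromosome" while
localizing or segmenting it badly.  Two quality signals fix the ranking:

* ``P_Box`` — regression confidence, ``1 - tanh(L_Reg)``, high when the box
  regression fit the target closely;
* ``IoU_Mask`` — the predicted IoU between the proposed mask and the truth.

The corrected score multiplies them into the classification confidence with
configurable exponents::

    score = P_Cls * IoU_Mask**alpha * P_Box**beta

Defaults are ``alpha=2`` (the squared mask-IoU factor) and ``beta=6`` (the
exponent found to rank best); both are exposed.

Suppression comes in two flavours.  Classic box NMS removes any detection
whose *box* IoU with a kept higher-scoring detection exceeds the threshold.
For thin curved objects two correct instances can share most of their
bounding boxes (box IoU ~0.8) while their masks barely overlap (mask IoU
~0.2), so box NMS deletes a true instance.  Mask NMS runs the same greedy
traversal on *mask* IoU and keeps both.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .geometry import Box, as_mask, box_iou

__all__ = [
    "Detection",
    "correct_confidence",
    "correct_detections",
    "mask_nms",
    "box_nms",
    "pairwise_mask_iou",
]

ScoreKey = Literal["raw", "corrected"]


@dataclass(frozen=True)
class Detection:
    """One predicted instance: geometry plus raw and corrected confidences.

    ``score`` is the corrected confidence; it is ``None`` until filled by
    :func:`correct_detections` (or set explicitly).
    """

    box: Box
    mask: np.ndarray
    p_cls: float
    p_box: float
    iou_mask_pred: float
    instance_id: int
    image_id: int = 0
    score: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", as_mask(self.mask))
        for name in ("p_cls", "p_box", "iou_mask_pred"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


def correct_confidence(
    p_cls: float,
    iou_mask: float,
    p_box: float,
    alpha: float = 2.0,
    beta: float = 6.0,
) -> float:
    """Corrected confidence ``p_cls * iou_mask**alpha * p_box**beta``.

    All inputs live in [0, 1] and the exponents are non-negative, so the
    result is again a probability, never above ``p_cls``.
    """
    for name, v in (("p_cls", p_cls), ("iou_mask", iou_mask), ("p_box", p_box)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if alpha < 0 or beta < 0:
        raise ValueError("exponents must be >= 0")
    return float(p_cls * iou_mask**alpha * p_box**beta)


def correct_detections(
    dets: Sequence[Detection], alpha: float = 2.0, beta: float = 6.0
) -> list[Detection]:
    """Fill the corrected ``score`` of every detection; raw fields untouched."""
    return [
        replace(
            d,
            score=correct_confidence(d.p_cls, d.iou_mask_pred, d.p_box, alpha, beta),
        )
        for d in dets
    ]


def pairwise_mask_iou(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Symmetric n x n matrix of mask IoUs (vectorized over flattened masks)."""
    if len(masks) == 0:
        return np.zeros((0, 0))
    flat = np.stack([as_mask(m).ravel() for m in masks]).astype(np.float64)
    inter = flat @ flat.T
    areas = flat.sum(axis=1)
    union = areas[:, None] + areas[None, :] - inter
    out = np.zeros_like(inter)
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    return out


def _score_of(d: Detection, score_key: ScoreKey) -> float:
    if score_key == "raw":
        return d.p_cls
    if d.score is None:
        raise ValueError(
            "detection has no corrected score; run correct_detections first "
            "or use score_key='raw'"
        )
    return d.score


def _greedy_nms(
    order: list[int], overlap: np.ndarray, iou_threshold: float
) -> list[int]:
    """Greedy suppression on a precomputed overlap matrix; strict comparator."""
    kept: list[int] = []
    suppressed = np.zeros(overlap.shape[0], dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        kept.append(i)
        suppressed |= overlap[i] > iou_threshold
        suppressed[i] = True
    return kept


def _validated_order(dets: Sequence[Detection], score_key: ScoreKey) -> list[int]:
    # Descending score; ties broken by lower instance_id for permutation
    # stability.
    image_ids = {d.image_id for d in dets}
    if len(image_ids) > 1:
        raise ValueError(f"detections span multiple images: {sorted(image_ids)}")
    shapes = {d.mask.shape for d in dets}
    if len(shapes) > 1:
        raise ValueError(f"detections on mixed grids: {sorted(shapes)}")
    return sorted(
        range(len(dets)),
        key=lambda i: (-_score_of(dets[i], score_key), dets[i].instance_id),
    )


def mask_nms(
    dets: Sequence[Detection],
    iou_threshold: float = 0.5,
    score_key: ScoreKey = "corrected",
    box_prefilter_threshold: float | None = None,
) -> list[int]:
    """Greedy NMS on mask IoU; returns kept indices in descending-score order.

    The highest-scoring remaining detection is kept and every remaining
    detection whose mask IoU with it strictly exceeds ``iou_threshold`` is
    removed; kept detections are therefore pairwise mask-IoU <= threshold.

    ``box_prefilter_threshold`` optionally runs a box-NMS pass first at a
    high threshold, purely for throughput; by default it is off so that as
    many proposals as possible reach the mask stage.
    """
    if not (0.0 <= iou_threshold <= 1.0):
        raise ValueError(f"iou_threshold must lie in [0, 1], got {iou_threshold}")
    if not dets:
        return []
    if box_prefilter_threshold is not None:
        surviving = box_nms(dets, box_prefilter_threshold, score_key)
    else:
        surviving = list(range(len(dets)))
    order = [i for i in _validated_order(dets, score_key) if i in set(surviving)]
    overlap = np.zeros((len(dets), len(dets)))
    sub = pairwise_mask_iou([dets[i].mask for i in surviving])
    for a, i in enumerate(surviving):
        overlap[i, surviving] = sub[a]
    return _greedy_nms(order, overlap, iou_threshold)


def box_nms(
    dets: Sequence[Detection],
    iou_threshold: float = 0.5,
    score_key: ScoreKey = "corrected",
) -> list[int]:
    """Greedy NMS on box IoU; the classic baseline comparator."""
    if not (0.0 <= iou_threshold <= 1.0):
        raise ValueError(f"iou_threshold must lie in [0, 1], got {iou_threshold}")
    if not dets:
        return []
    order = _validated_order(dets, score_key)
    n = len(dets)
    overlap = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            overlap[i, j] = overlap[j, i] = box_iou(dets[i].box, dets[j].box)
    return _greedy_nms(order, overlap, iou_threshold)
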