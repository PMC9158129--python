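"""Loss functions for regression-corrected instance segmentation.

The segmentation objective family is built on the log-IoU loss
``L_IoU = -ln IoU`` and its partitioned refinement

    L_K-IoU = -sum_i delta_i * ln(IoU_i),

where the ground-truth mask is divided into K cells (see
:func:`chromoseg.geometry.partition_grid`), ``IoU_i`` is the prediction/truth
IoU restricted to cell ``i`` and ``delta_i`` the cell's share of the ground
truth.  A plain IoU loss lets well-segmented regions of an elongated object
wash out a gross local error; the partitioned loss charges each cell its own
log-penalty so a single badly segmented cell cannot hide behind the rest.
The unweighted variant (``delta_i = 1`` on every non-trivial cell) is the
harshest reading and bounds the weighted one from above.

The box side contributes a Smooth-L1 regression loss and the derived
regression confidence ``P_Box = 1 - tanh(L_Reg)``, a monotone map of the
regression loss onto ``(0, 1]`` used downstream as a localization-quality
score.  The composite per-proposal ledger is

    L = L_Box + L_Seg,   L_Box = L_Cls + L_Reg + L_PBox,
                         L_Seg = L_Mask + L_K-IoU + L_IoUMask.

Every logarithm is clamped at ``eps`` (default 1e-7) so the losses stay
finite even for fully disjoint masks; with fine partition grids empty cells
would otherwise produce infinities and dead gradients.

Masks may be boolean or probability-valued: float masks in ``[0, 1]`` are
scored with the soft intersection ``sum(p*g)`` and union ``sum(p+g-p*g)``, so
the same functions serve as differentiable training objectives.  Boolean
masks are the default, tested contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import EmptyMaskError, PartitionSpec, per_part_iou

__all__ = [
    "DEFAULT_EPS",
    "LossComponents",
    "iou_loss",
    "k_iou_loss",
    "smooth_l1",
    "p_box",
    "binary_cross_entropy",
    "head_supervision_losses",
    "aggregate_losses",
]

DEFAULT_EPS = 1e-7


@dataclass(frozen=True)
class LossComponents:
    """Per-proposal loss ledger: box-head terms, seg-head terms and totals."""

    l_cls: float
    l_reg: float
    l_pbox: float
    l_mask: float
    l_kiou: float
    l_ioumask: float
    l_box: float
    l_seg: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return {
            "l_cls": self.l_cls,
            "l_reg": self.l_reg,
            "l_pbox": self.l_pbox,
            "l_mask": self.l_mask,
            "l_kiou": self.l_kiou,
            "l_ioumask": self.l_ioumask,
            "l_box": self.l_box,
            "l_seg": self.l_seg,
            "total": self.total,
        }


def _coerce_mask(m: np.ndarray) -> np.ndarray:
    """Accept boolean or probability-valued masks; return float or bool array."""
    m = np.asarray(m)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    if m.dtype == bool:
        return m
    if np.isin(m, (0, 1)).all():
        return m.astype(bool)
    if (m < 0).any() or (m > 1).any() or not np.isfinite(m).all():
        raise ValueError("probability mask values must lie in [0, 1]")
    return m.astype(float)


def _soft_iou(pred: np.ndarray, gt: np.ndarray, where: np.ndarray | None = None) -> float:
    """IoU with soft intersection/union; exact pixel IoU on boolean inputs."""
    p = pred.astype(float)
    g = gt.astype(float)
    if where is not None:
        p = p[where]
        g = g[where]
    inter = float(np.sum(p * g))
    union = float(np.sum(p + g) - inter)
    if union == 0.0:
        return 0.0
    return inter / union


def iou_loss(pred: np.ndarray, gt: np.ndarray, eps: float = DEFAULT_EPS) -> float:
    """Log-IoU loss ``-ln(max(IoU, eps))``; zero iff the masks coincide."""
    pred = _coerce_mask(pred)
    gt = _coerce_mask(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shape mismatch: {pred.shape} vs {gt.shape}")
    if not gt.any():
        raise EmptyMaskError("iou_loss requires a non-empty ground truth")
    return -float(np.log(max(_soft_iou(pred, gt), eps)))


def k_iou_loss(
    pred: np.ndarray,
    gt: np.ndarray,
    part: PartitionSpec,
    weighted: bool = True,
    eps: float = DEFAULT_EPS,
) -> float:
    """Partitioned log-IoU loss over the K cells of ``part``.

    With ``weighted=True`` each cell's ``-ln IoU_i`` is scaled by its
    ground-truth share ``delta_i``; with ``weighted=False`` every cell that
    contains ground truth counts with weight one (the harsher variant).
    Cells with no ground truth contribute nothing either way.
    """
    pred = _coerce_mask(pred)
    gt = _coerce_mask(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shape mismatch: {pred.shape} vs {gt.shape}")
    if not gt.any():
        raise EmptyMaskError("k_iou_loss requires a non-empty ground truth")
    if part.cell_of_pixel.shape != gt.shape:
        raise ValueError(
            f"partition grid {part.cell_of_pixel.shape} does not match "
            f"mask grid {gt.shape}"
        )
    if pred.dtype == bool and gt.dtype == bool:
        ious = per_part_iou(pred, gt, part)
    else:
        ious = np.zeros(part.k)
        for i in range(part.k):
            cell = part.cell_of_pixel == i
            ious[i] = _soft_iou(pred, gt, where=cell)
    active = part.delta > 0
    w = part.delta[active] if weighted else np.ones(np.count_nonzero(active))
    return float(-(w * np.log(np.maximum(ious[active], eps))).sum())


def smooth_l1(predicted: np.ndarray, target: np.ndarray) -> float:
    """Smooth-L1 regression loss, averaged over the 4 box offsets.

    ``s(d) = 0.5 d^2`` for ``|d| < 1``, else ``|d| - 0.5``.  The mean keeps
    the loss scale comparable across offset parameterizations.
    """
    predicted = np.asarray(predicted, dtype=float)
    target = np.asarray(target, dtype=float)
    if predicted.shape != (4,) or target.shape != (4,):
        raise ValueError("box offsets must be length-4 vectors")
    if not (np.isfinite(predicted).all() and np.isfinite(target).all()):
        raise ValueError("box offsets must be finite")
    d = np.abs(predicted - target)
    per_coord = np.where(d < 1.0, 0.5 * d * d, d - 0.5)
    return float(per_coord.mean())


def p_box(l_reg: float) -> float:
    """Regression confidence ``1 - tanh(L_Reg)``.

    A strictly decreasing bijection from ``[0, inf)`` onto ``(0, 1]``: a
    perfect regression (zero loss) maps to confidence 1, and confidence
    decays towards 0 as the regression loss grows.
    """
    l_reg = float(l_reg)
    if not np.isfinite(l_reg) or l_reg < 0:
        raise ValueError(f"regression loss must be finite and >= 0, got {l_reg}")
    # 1 - tanh(x) = 2 / (1 + e^{2x}); this form stays strictly positive far
    # beyond the point where tanh saturates to 1 in float64
    return float(2.0 / (1.0 + np.exp(2.0 * min(l_reg, 350.0))))


def binary_cross_entropy(pred: float, target: float, eps: float = DEFAULT_EPS) -> float:
    """BCE ``-t ln p - (1-t) ln(1-p)`` with probabilities clamped by eps."""
    pred = float(pred)
    target = float(target)
    if not (0.0 <= pred <= 1.0 and 0.0 <= target <= 1.0):
        raise ValueError("BCE inputs must lie in [0, 1]")
    p = min(max(pred, eps), 1.0 - eps)
    return -(target * np.log(p) + (1.0 - target) * np.log(1.0 - p))


def head_supervision_losses(
    p_cls_pred: float,
    cls_target: int,
    pbox_pred: float,
    pbox_target: float,
    mask_pred: np.ndarray,
    mask_target: np.ndarray,
    iou_pred: float,
    iou_true: float,
    eps: float = DEFAULT_EPS,
) -> tuple[float, float, float, float]:
    """Supervision terms for the classification, P_Box, mask and mask-IoU heads.

    Returns ``(l_cls, l_pbox, l_mask, l_ioumask)``: binary cross-entropy for
    the classification head against its 0/1 target and for the P_Box head
    against the regression-derived confidence target; mean per-pixel binary
    cross-entropy for the mask head; squared error against the true mask IoU
    for the mask-IoU head.
    """
    if cls_target not in (0, 1):
        raise ValueError("classification target must be 0 or 1")
    mask_pred = np.asarray(mask_pred, dtype=float)
    mask_target = _coerce_mask(mask_target)
    if mask_pred.shape != mask_target.shape:
        raise ValueError(
            f"mask shape mismatch: {mask_pred.shape} vs {mask_target.shape}"
        )
    if (mask_pred < 0).any() or (mask_pred > 1).any():
        raise ValueError("mask probabilities must lie in [0, 1]")
    if not (0.0 <= iou_pred <= 1.0 and 0.0 <= iou_true <= 1.0):
        raise ValueError("IoU values must lie in [0, 1]")

    l_cls = binary_cross_entropy(p_cls_pred, cls_target, eps)
    l_pbox = binary_cross_entropy(pbox_pred, pbox_target, eps)
    p = np.clip(mask_pred, eps, 1.0 - eps)
    g = mask_target.astype(float)
    l_mask = float(-(g * np.log(p) + (1.0 - g) * np.log(1.0 - p)).mean())
    l_ioumask = (float(iou_pred) - float(iou_true)) ** 2
    return float(l_cls), float(l_pbox), l_mask, l_ioumask


def aggregate_losses(
    l_cls: float,
    l_reg: float,
    l_pbox: float,
    l_mask: float,
    l_kiou: float,
    l_ioumask: float,
) -> LossComponents:
    """Assemble the composite per-proposal ledger ``L = L_Box + L_Seg``."""
    parts = dict(
        l_cls=l_cls, l_reg=l_reg, l_pbox=l_pbox,
        l_mask=l_mask, l_kiou=l_kiou, l_ioumask=l_ioumask,
    )
    for name, v in parts.items():
        v = float(v)
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    l_box = float(l_cls) + float(l_reg) + float(l_pbox)
    l_seg = float(l_mask) + float(l_kiou) + float(l_ioumask)
    return LossComponents(
        l_cls=float(l_cls),
        l_reg=float(l_reg),
        l_pbox=float(l_pbox),
        l_mask=float(l_mask),
        l_kiou=float(l_kiou),
        l_ioumask=float(l_ioumask),
        l_box=l_box,
        l_seg=l_seg,
        total=l_box + l_seg,
    )
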