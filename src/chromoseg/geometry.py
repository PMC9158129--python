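"""Mask and box geometry underlying the partitioned IoU loss.

All masks are 2-D boolean :class:`numpy.ndarray` grids in row-major order.
Boxes use 0-based, half-open pixel coordinates ``[x1, x2) x [y1, y2)`` — one
convention, used everywhere in the package including RLE serialization.

The central construct is :func:`partition_grid`: the tight bounding box of a
ground-truth mask is split into ``rows x cols`` near-equal cells and the
boundary cells are extended outward so that the cells tile the entire image.
Each cell ``i`` carries a weight ``delta_i``, the share of ground-truth pixels
it contains; the weights of a non-empty mask sum to one.  Restricting both the
prediction and the ground truth to each cell and scoring IoU per cell is what
turns the plain ``-ln IoU`` objective into its K-part counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Box",
    "PartitionSpec",
    "EmptyMaskError",
    "as_mask",
    "mask_iou",
    "box_iou",
    "mask_to_box",
    "partition_grid",
    "per_part_iou",
]


class EmptyMaskError(ValueError):
    """Raised when an operation requires a non-empty mask."""


@dataclass(frozen=True)
class Box:
    """Axis-aligned box, 0-based half-open: ``[x1, x2) x [y1, y2)``.

    Coordinates are floats in pixel units; a valid box has strictly positive
    area.
    """

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.x1, self.y1, self.x2, self.y2])):
            raise ValueError("box coordinates must be finite")
        if self.x2 <= self.x1 or self.y2 <= self.y1:
            raise ValueError(
                f"degenerate box: ({self.x1}, {self.y1}, {self.x2}, {self.y2})"
            )

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.x2, self.y2)


@dataclass(frozen=True)
class PartitionSpec:
    """K-cell division of an image grid with per-cell ground-truth weights.

    Attributes
    ----------
    rows, cols
        Grid shape of the partition; ``K = rows * cols``.
    cell_of_pixel
        Integer array of the image's shape mapping every pixel to its cell
        index in ``0..K-1`` (row-major cell numbering).  Cells tile the plane:
        every pixel belongs to exactly one cell.
    delta
        Length-K weight vector; ``delta[i]`` is the fraction of ground-truth
        pixels falling in cell ``i``.  Sums to 1 for a non-empty ground truth
        and is zero exactly on cells containing no ground-truth pixel.
    """

    rows: int
    cols: int
    cell_of_pixel: np.ndarray
    delta: np.ndarray

    @property
    def k(self) -> int:
        return self.rows * self.cols


def as_mask(m: np.ndarray) -> np.ndarray:
    """Validate and return ``m`` as a 2-D boolean array."""
    m = np.asarray(m)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    if m.dtype != bool:
        if not np.isin(m, (0, 1)).all():
            raise ValueError("mask values must be strictly 0/1")
        m = m.astype(bool)
    return m


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Pixel IoU ``|a & b| / |a | b|`` of two same-shape binary masks.

    Two empty masks score 0 by convention (an empty/empty cell never carries
    weight in the partitioned loss, and 0 avoids spurious perfect scores).
    """
    a = as_mask(a)
    b = as_mask(b)
    _check_same_shape(a, b)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def box_iou(a: Box, b: Box) -> float:
    """IoU of two boxes under the half-open convention."""
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def mask_to_box(m: np.ndarray) -> Box:
    """Tight half-open bounding box of the true pixels of ``m``."""
    m = as_mask(m)
    rows = np.flatnonzero(m.any(axis=1))
    if rows.size == 0:
        raise EmptyMaskError("cannot take the bounding box of an empty mask")
    cols = np.flatnonzero(m.any(axis=0))
    return Box(
        x1=float(cols[0]),
        y1=float(rows[0]),
        x2=float(cols[-1] + 1),
        y2=float(rows[-1] + 1),
    )


def _split_edges(start: int, stop: int, n: int) -> np.ndarray:
    """Interior edges splitting ``[start, stop)`` into n near-equal runs.

    Runs differ in length by at most one pixel; the longer runs come first
    (top/left), which makes uneven splits deterministic.
    """
    length = stop - start
    base, rem = divmod(length, n)
    sizes = np.full(n, base, dtype=np.int64)
    sizes[:rem] += 1
    return start + np.cumsum(sizes)[:-1]


def partition_grid(gt: np.ndarray, rows: int, cols: int) -> PartitionSpec:
    """Partition the image into ``rows x cols`` cells around the gt mask.

    The tight bounding box of ``gt`` is cut into near-equal integer cells;
    boundary cells absorb every pixel outside the bounding box, so the cells
    tile the whole image and stray predicted pixels are always charged to
    exactly one cell.  ``delta[i]`` is the ground-truth share of cell ``i``.
    """
    gt = as_mask(gt)
    if rows < 1 or cols < 1:
        raise ValueError(f"partition shape must be >= 1x1, got {rows}x{cols}")
    if not gt.any():
        raise EmptyMaskError("cannot partition an empty ground-truth mask")
    box = mask_to_box(gt)
    h, w = gt.shape
    row_edges = _split_edges(int(box.y1), int(box.y2), rows)
    col_edges = _split_edges(int(box.x1), int(box.x2), cols)
    # searchsorted against interior edges extends the first/last cells to the
    # image border automatically.
    row_cell = np.searchsorted(row_edges, np.arange(h), side="right")
    col_cell = np.searchsorted(col_edges, np.arange(w), side="right")
    cell_of_pixel = (row_cell[:, None] * cols + col_cell[None, :]).astype(np.int64)

    k = rows * cols
    counts = np.bincount(cell_of_pixel[gt], minlength=k)
    delta = counts / counts.sum()
    return PartitionSpec(rows=rows, cols=cols, cell_of_pixel=cell_of_pixel, delta=delta)


def per_part_iou(pred: np.ndarray, gt: np.ndarray, part: PartitionSpec) -> np.ndarray:
    """Per-cell IoU of ``pred`` vs ``gt`` restricted to each partition cell.

    Cell ``i`` scores ``|pred_i & gt_i| / |pred_i | gt_i|``; a cell empty in
    both masks scores 0 (the empty/empty convention).
    """
    pred = as_mask(pred)
    gt = as_mask(gt)
    _check_same_shape(pred, gt)
    if part.cell_of_pixel.shape != gt.shape:
        raise ValueError(
            f"partition grid {part.cell_of_pixel.shape} does not match "
            f"mask grid {gt.shape}"
        )
    k = part.k
    inter = np.bincount(part.cell_of_pixel[pred & gt], minlength=k)
    union = np.bincount(part.cell_of_pixel[pred | gt], minlength=k)
    out = np.zeros(k, dtype=float)
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    return out
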