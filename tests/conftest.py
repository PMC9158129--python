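"""Shared fixtures: random mask/box/detection factories, all explicitly seeded."""

from __future__ import annotations

import numpy as np
import pytest

from chromoseg import Box, Detection, mask_to_box


def random_mask(
    rng: np.random.Generator,
    shape: tuple[int, int] = (32, 32),
    nonempty: bool = False,
) -> np.ndarray:
    """Union of a few random rectangles plus salt pixels."""
    h, w = shape
    m = np.zeros(shape, dtype=bool)
    for _ in range(rng.integers(1, 4)):
        r0, c0 = rng.integers(0, h - 1), rng.integers(0, w - 1)
        r1 = rng.integers(r0 + 1, h + 1)
        c1 = rng.integers(c0 + 1, w + 1)
        m[r0:r1, c0:c1] = True
    m ^= rng.random(shape) < 0.02
    if nonempty and not m.any():
        m[rng.integers(0, h), rng.integers(0, w)] = True
    return m


def random_box(rng: np.random.Generator, extent: float = 100.0) -> Box:
    x1, y1 = rng.uniform(0, extent - 2, size=2)
    return Box(x1, y1, x1 + rng.uniform(1, extent - x1), y1 + rng.uniform(1, extent - y1))


def random_detections(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int] = (24, 24),
    tie_scores: bool = False,
) -> list[Detection]:
    dets = []
    for i in range(n):
        m = random_mask(rng, shape, nonempty=True)
        score = float(rng.random())
        if tie_scores:
            score = round(score, 1)
        dets.append(
            Detection(
                box=mask_to_box(m),
                mask=m,
                p_cls=float(rng.random()),
                p_box=float(rng.random()),
                iou_mask_pred=float(rng.random()),
                instance_id=i,
                score=score,
            )
        )
    return dets


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
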