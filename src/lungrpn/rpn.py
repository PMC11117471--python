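"""Region-proposal geometry: anchor grids, IoU, anchor labelling, offset coding, NMS.

All boxes are axis-aligned pixel rectangles in 0-based, half-open coordinates
(``x_max``/``y_max`` exclusive), so the area of a box is simply
``(x_max - x_min) * (y_max - y_min)``.  The region-proposal network of a
two-stage detector tiles a set of prior shapes ("anchors") over the cells of a
downsampled feature map, scores each tiled box as target/background, and
regresses a 4-vector of offsets that deforms the anchor into the predicted
box.  This module implements every geometric primitive of that contract; it
contains no learned components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Box",
    "ScoredBox",
    "RPNConfig",
    "iou",
    "iou_matrix",
    "generate_anchor_grid",
    "label_anchors",
    "encode_offsets",
    "decode_offsets",
    "nms",
    "select_proposals",
    "POSITIVE",
    "NEGATIVE",
    "IGNORE",
]

POSITIVE = 1
NEGATIVE = 0
IGNORE = -1


@dataclass(frozen=True)
class Box:
    """Axis-aligned pixel rectangle, 0-based, half-open."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def as_array(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max], dtype=float)


@dataclass(frozen=True)
class ScoredBox:
    box: Box
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class RPNConfig:
    """Thresholds of the proposal stage.

    ``pos_iou``/``neg_iou`` split anchors into positive, negative and ignored
    training samples; ``nms_iou`` is the greedy-suppression overlap; ``top_n``
    caps the number of surviving proposals per image.
    """

    pos_iou: float = 0.7
    neg_iou: float = 0.3
    nms_iou: float = 0.7
    top_n: int = 300

    def __post_init__(self) -> None:
        if not (0.0 <= self.neg_iou < self.pos_iou <= 1.0):
            raise ValueError("require 0 <= neg_iou < pos_iou <= 1")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes, in [0, 1]."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def _boxes_to_array(boxes: Sequence[Box]) -> np.ndarray:
    if len(boxes) == 0:
        return np.zeros((0, 4), dtype=float)
    return np.stack([b.as_array() for b in boxes])


def iou_matrix(a: Sequence[Box], b: Sequence[Box]) -> np.ndarray:
    """Pairwise IoU, shape (len(a), len(b))."""
    A, B = _boxes_to_array(a), _boxes_to_array(b)
    if A.shape[0] == 0 or B.shape[0] == 0:
        return np.zeros((A.shape[0], B.shape[0]))
    ix = np.minimum(A[:, None, 2], B[None, :, 2]) - np.maximum(A[:, None, 0], B[None, :, 0])
    iy = np.minimum(A[:, None, 3], B[None, :, 3]) - np.maximum(A[:, None, 1], B[None, :, 1])
    inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
    area_a = (A[:, 2] - A[:, 0]) * (A[:, 3] - A[:, 1])
    area_b = (B[:, 2] - B[:, 0]) * (B[:, 3] - B[:, 1])
    return inter / (area_a[:, None] + area_b[None, :] - inter)


def generate_anchor_grid(
    feature_shape: tuple[int, int], stride: float, anchors: "AnchorSet | Iterable"
) -> list[Box]:
    """Tile anchor shapes over a feature grid.

    One box per (cell, shape), centred at ``((j + 0.5) * stride, (i + 0.5) * stride)``
    for cell row i, column j.  Returns ``H * W * K`` boxes ordered row-major by
    cell, then by shape.
    """
    shapes = getattr(anchors, "shapes", anchors)
    shapes = [(float(s[0]), float(s[1])) for s in shapes]
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if len(shapes) == 0:
        raise ValueError("empty anchor set")
    h, w = feature_shape
    boxes: list[Box] = []
    for i in range(h):
        cy = (i + 0.5) * stride
        for j in range(w):
            cx = (j + 0.5) * stride
            for bw, bh in shapes:
                boxes.append(Box(cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2))
    return boxes


def label_anchors(
    anchors: Sequence[Box], gt: Sequence[Box], config: RPNConfig
) -> np.ndarray:
    """Assign positive / negative / ignore training labels to anchors.

    An anchor is positive when its IoU with some ground-truth box reaches
    ``pos_iou``, or when it is the best-overlapping anchor for a ground-truth
    box (so every object recruits at least one positive even if all overlaps
    are low).  Anchors below ``neg_iou`` against everything are negative; the
    rest are ignored.
    """
    n = len(anchors)
    if len(gt) == 0:
        return np.full(n, NEGATIVE, dtype=int)
    m = iou_matrix(anchors, gt)  # (n_anchors, n_gt)
    labels = np.full(n, IGNORE, dtype=int)
    max_per_anchor = m.max(axis=1)
    labels[max_per_anchor < config.neg_iou] = NEGATIVE
    labels[max_per_anchor >= config.pos_iou] = POSITIVE
    # argmax rule: the best anchor for each GT is positive regardless of threshold
    best_for_gt = m.argmax(axis=0)
    labels[best_for_gt] = POSITIVE
    return labels


def encode_offsets(gt: Box, anchor: Box) -> np.ndarray:
    """Regression target (dx, dy, dw, dh) taking ``anchor`` onto ``gt``.

    The standard parameterisation: centre shifts normalised by the anchor
    size, and log ratios of widths/heights.
    """
    if anchor.width <= 0 or anchor.height <= 0:
        raise ValueError("anchor must have positive dimensions")
    acx, acy = anchor.center
    gcx, gcy = gt.center
    return np.array(
        [
            (gcx - acx) / anchor.width,
            (gcy - acy) / anchor.height,
            np.log(gt.width / anchor.width),
            np.log(gt.height / anchor.height),
        ]
    )


def decode_offsets(offsets: Sequence[float], anchor: Box) -> Box:
    """Inverse of :func:`encode_offsets`; zero offsets return the anchor."""
    dx, dy, dw, dh = (float(v) for v in offsets)
    acx, acy = anchor.center
    cx = acx + dx * anchor.width
    cy = acy + dy * anchor.height
    w = anchor.width * np.exp(dw)
    h = anchor.height * np.exp(dh)
    return Box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


def nms(boxes: Sequence[ScoredBox], iou_threshold: float) -> list[ScoredBox]:
    """Greedy non-maximum suppression.

    Boxes are visited in descending score (score ties broken lexicographically
    on box coordinates, then input index, so the survivor set does not depend
    on input order); a box is kept iff its IoU with every already-kept box is
    below the threshold.  Survivors are returned in descending score.
    """
    order = sorted(
        range(len(boxes)),
        key=lambda i: (-boxes[i].score, boxes[i].box.as_array().tolist(), i),
    )
    kept: list[ScoredBox] = []
    for i in order:
        cand = boxes[i]
        if all(iou(cand.box, k.box) < iou_threshold for k in kept):
            kept.append(cand)
    return kept


def select_proposals(scored: Sequence[ScoredBox], config: RPNConfig) -> list[ScoredBox]:
    """Proposal selection: NMS, then keep the ``top_n`` highest scores."""
    return nms(scored, config.nms_iou)[: config.top_n]
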