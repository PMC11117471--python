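"""Detection metrics: IoU matching, the five indicators, k-fold splitting.

A detection run is reduced to confusion counts by greedy one-to-one matching
of scored detections against ground-truth boxes at an IoU threshold; from
TP/FP/TN/FN the five standard indicators follow:

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)          (= recall)
    specificity = TN / (FP + TN)
    F1          = 2 * precision * recall / (precision + recall)

True negatives only exist at the candidate level — a candidate region that
is neither a nodule nor flagged as one — so the number of evaluated negative
candidates is an explicit input to the accounting, never inferred.  A metric
with a zero denominator is reported as NaN (an explicit "undefined" flag),
never silently as 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold

from .rpn import Box, ScoredBox, iou_matrix

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "MatchConfig",
    "match_detections",
    "compute_metrics",
    "f1_from_pr",
    "kfold_split",
    "pool_counts",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The five indicators; NaN marks an undefined (zero-denominator) metric."""

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float

    def as_dict(self) -> dict[str, float | None]:
        return {k: (None if math.isnan(v) else v) for k, v in asdict(self).items()}

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)


@dataclass(frozen=True)
class MatchConfig:
    """IoU threshold at which a detection counts as hitting a ground-truth box."""

    iou_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.iou_threshold <= 1.0):
            raise ValueError("iou_threshold must lie in (0, 1]")


def match_detections(
    dets: Sequence[ScoredBox],
    gts: Sequence[Box],
    cfg: MatchConfig = MatchConfig(),
    negatives_evaluated: int = 0,
) -> ConfusionCounts:
    """Greedy score-descending one-to-one matching.

    Each detection, in descending score (ties by lower index), claims the
    unused ground-truth box of highest IoU provided it reaches the threshold;
    matched pairs are TPs, unmatched detections FPs, unmatched ground truths
    FNs.  TN = negatives_evaluated - FP (candidate-level accounting); an
    inconsistent count (fewer evaluated negatives than FPs) raises.
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    used = np.zeros(len(gts), dtype=bool)
    tp = 0
    if len(dets) and len(gts):
        m = iou_matrix([d.box for d in dets], list(gts))
    else:
        m = np.zeros((len(dets), len(gts)))
    for i in order:
        if not len(gts):
            break
        overlaps = np.where(used, -1.0, m[i])
        j = int(np.argmax(overlaps))
        if overlaps[j] >= cfg.iou_threshold:
            used[j] = True
            tp += 1
    fp = len(dets) - tp
    fn = len(gts) - tp
    if negatives_evaluated < fp:
        raise ValueError(
            f"negatives_evaluated={negatives_evaluated} is fewer than the {fp} false positives"
        )
    return ConfusionCounts(tp=tp, fp=fp, tn=negatives_evaluated - fp, fn=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """The five indicators from confusion counts; zero denominators give NaN."""
    if c.total == 0:
        raise ValueError("all-zero confusion counts: nothing was evaluated")
    precision = _ratio(c.tp, c.tp + c.fp)
    sensitivity = _ratio(c.tp, c.tp + c.fn)
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        f1 = math.nan
    else:
        f1 = f1_from_pr(precision, sensitivity)
    return MetricsReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=precision,
        sensitivity=sensitivity,
        specificity=_ratio(c.tn, c.fp + c.tn),
        f1=f1,
    )


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall <= 0:
        raise ValueError("precision + recall must be positive")
    return 2.0 * precision * recall / (precision + recall)


def kfold_split(n_items: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Shuffled k-fold assignment: array of fold ids in [0, k), sizes differ <= 1."""
    if k > n_items:
        raise ValueError(f"k={k} exceeds n_items={n_items}")
    assignment = np.empty(n_items, dtype=int)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(kf.split(np.arange(n_items))):
        assignment[test_idx] = fold
    return assignment


def pool_counts(counts: Sequence[ConfusionCounts]) -> ConfusionCounts:
    """Sum per-fold confusion counts into a pooled table."""
    total = ConfusionCounts()
    for c in counts:
        total = total + c
    return total
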