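"""Detection-quality and interrater-agreement statistics.

Cohen's kappa for chance-corrected agreement between two raters of the
same frames (human vs. model per section), class confusion matrices with
a background class for unmatched boxes, and IoU-matched average precision
(greedy matching in descending confidence, all-points interpolated
precision-recall area) for bounding-box detections.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "AgreementResult",
    "ConfusionMatrix",
    "APResult",
    "Box",
    "cohens_kappa",
    "confusion",
    "iou",
    "match_and_ap",
]


@dataclass(frozen=True)
class AgreementResult:
    """Cohen's kappa with its ingredients.

    kappa = (p_o - p_e) / (1 - p_e); ``degenerate`` flags the p_e = 1 case
    (both raters constant and identical), where kappa is defined as 1.
    """

    kappa: float
    p_o: float
    p_e: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts matrix over (truth row, prediction column) class pairs."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def normalized(self) -> np.ndarray:
        """Row-normalized matrix; all-zero rows stay zero."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            out = np.where(totals > 0, self.counts / totals, 0.0)
        return out

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class APResult:
    """Per-class average precision and their mean, at one IoU threshold."""

    per_class: dict[str, float]
    map: float
    iou_threshold: float
    degenerate_classes: tuple[str, ...] = ()


@dataclass(frozen=True)
class Box:
    """Axis-aligned box: top-left corner plus size, pixel units."""

    x: float
    y: float
    w: float
    h: float
    cls: str = ""
    conf: float = 1.0

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box width and height must be positive")


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> AgreementResult:
    """Chance-corrected agreement between two equal-length label sequences.

    p_o is the observed agreement fraction; p_e the expected agreement
    under independent raters with the observed marginals.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("label sequences must have equal length")
    if len(a) == 0:
        raise ValueError("label sequences must be non-empty")
    n = len(a)
    p_o = float(np.mean(a == b))
    classes = sorted(set(a.tolist()) | set(b.tolist()), key=str)
    ca = Counter(a.tolist())
    cb = Counter(b.tolist())
    p_e = float(sum((ca[c] / n) * (cb[c] / n) for c in classes))
    if p_e >= 1.0 - 1e-12:
        # both raters constant and identical: agreement is perfect but
        # chance correction is undefined; report kappa = 1, flagged
        return AgreementResult(1.0, p_o, 1.0, n, degenerate=True)
    kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(float(kappa), p_o, p_e, n)


def confusion(truth_labels: Sequence, pred_labels: Sequence,
              classes: Sequence[str] | None = None,
              background: str = "background") -> ConfusionMatrix:
    """Counts of (truth, prediction) pairs.

    ``None`` entries stand for unmatched items: a None truth puts the
    prediction in the background row, a None prediction puts the truth in
    the background column.
    """
    if len(truth_labels) != len(pred_labels):
        raise ValueError("label sequences must have equal length")
    t = [background if x is None else x for x in truth_labels]
    p = [background if x is None else x for x in pred_labels]
    if classes is None:
        seen = sorted(set(t) | set(p) - {background}, key=str)
        classes = [c for c in seen if c != background] + [background]
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for ti, pi in zip(t, p):
        counts[index[ti], index[pi]] += 1
    return ConfusionMatrix(classes, counts)


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes."""
    x0 = max(a.x, b.x)
    y0 = max(a.y, b.y)
    x1 = min(a.x + a.w, b.x + b.w)
    y1 = min(a.y + a.h, b.y + b.h)
    if x1 <= x0 or y1 <= y0:
        return 0.0
    inter = (x1 - x0) * (y1 - y0)
    union = a.w * a.h + b.w * b.h - inter
    return inter / union


def _class_ap(preds: list[Box], truths: list[Box], thr: float) -> float:
    """AP for one class: greedy confidence-descending match, all-points PR area."""
    n_truth = len(truths)
    if n_truth == 0:
        return 0.0
    order = sorted(range(len(preds)), key=lambda i: -preds[i].conf)
    matched = [False] * n_truth
    tp = np.zeros(len(preds))
    for rank, i in enumerate(order):
        best_j, best_iou = -1, thr
        for j, t in enumerate(truths):
            if matched[j]:
                continue
            v = iou(preds[i], t)
            if v >= best_iou:
                best_iou, best_j = v, j
        if best_j >= 0:
            matched[best_j] = True
            tp[rank] = 1.0
    cum_tp = np.cumsum(tp)
    recall = cum_tp / n_truth
    precision = cum_tp / np.arange(1, len(preds) + 1)
    # all-points interpolation: precision envelope integrated over recall
    r = np.concatenate(([0.0], recall, [recall[-1] if len(recall) else 0.0]))
    p = np.concatenate(([1.0], precision, [0.0]))
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.where(np.diff(r) > 0)[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def match_and_ap(predictions: Sequence[Box], truths: Sequence[Box],
                 iou_threshold: float = 0.5) -> APResult:
    """Per-class average precision and mAP at one IoU threshold.

    Predictions are matched greedily in descending confidence; each truth
    box matches at most once and a match requires IoU >= threshold. A
    class with predictions but no truth boxes scores AP 0 and is flagged
    in ``degenerate_classes``.
    """
    if not 0 < iou_threshold <= 1:
        raise ValueError("iou_threshold must lie in (0, 1]")
    classes = sorted({b.cls for b in truths} | {b.cls for b in predictions})
    per_class: dict[str, float] = {}
    degenerate: list[str] = []
    for c in classes:
        p = [b for b in predictions if b.cls == c]
        t = [b for b in truths if b.cls == c]
        if not t:
            per_class[c] = 0.0
            if p:
                degenerate.append(c)
            continue
        if not p:
            per_class[c] = 0.0
            continue
        per_class[c] = _class_ap(p, t, iou_threshold)
    m = float(np.mean(list(per_class.values()))) if per_class else 0.0
    return APResult(per_class, m, iou_threshold, tuple(degenerate))
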