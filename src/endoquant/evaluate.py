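"""Detection-quality evaluation: IoU matching, precision/recall/F1 per score
threshold, and average precision.

A prediction is a true positive iff it has mask IoU strictly greater than
0.5 with an as-yet-unmatched ground-truth object; matching is greedy in
descending score order with each ground truth consumable once. The
precision-recall curve is built from equal-count score bins: the sorted
prediction scores are split into 100 bins of (near-)equal size, each bin's
maximum score defines a threshold, and precision/recall/F1 are computed
over the predictions with score >= that threshold. Average precision is the
trapezoidal area under the (recall, precision) points, extrapolated to
(recall=0, precision=1) and *not* extrapolated beyond the maximum observed
recall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import Detection, Mask, iou

IOU_THRESHOLD = 0.5
N_BINS = 100


@dataclass
class MatchResult:
    """Outcome of matching predictions against ground truth."""

    tp_pairs: list[tuple[int, int]]  # (prediction index, ground-truth index)
    fp: list[int]  # unmatched prediction indices
    fn: list[int]  # unmatched ground-truth indices

    @property
    def n_tp(self) -> int:
        return len(self.tp_pairs)


@dataclass
class EvaluationCurve:
    """Precision-recall-F1 as a function of ascending score thresholds."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    ap: float = field(default=np.nan)

    def __post_init__(self) -> None:
        n = len(self.thresholds)
        if not (len(self.precision) == len(self.recall) == len(self.f1) == n):
            raise ValueError("curve arrays must have equal length")


def _iou_table(preds: list[Detection], gts: list[Mask]) -> dict[tuple[int, int], float]:
    """Sparse pairwise IoU over bbox-intersecting (prediction, gt) pairs."""
    gt_boxes = [g.bbox() for g in gts]
    table: dict[tuple[int, int], float] = {}
    for i, p in enumerate(preds):
        for j, gb in enumerate(gt_boxes):
            if p.bbox.intersects(gb):
                v = iou(p.mask, gts[j])
                if v > 0:
                    table[(i, j)] = v
    return table


def match_detections(
    preds: list[Detection],
    gts: list[Mask],
    iou_thr: float = IOU_THRESHOLD,
    _iou_cache: dict[tuple[int, int], float] | None = None,
    _pred_indices: list[int] | None = None,
) -> MatchResult:
    """Greedy one-to-one matching of predictions to ground truth.

    Predictions are visited in descending score order; each takes its best
    still-available ground truth and is a true positive iff that IoU is
    strictly above ``iou_thr``. A ground truth can be matched at most once.
    """
    indices = _pred_indices if _pred_indices is not None else list(range(len(preds)))
    table = _iou_cache if _iou_cache is not None else _iou_table(preds, gts)
    order = sorted(indices, key=lambda i: (-preds[i].score, i))
    gt_taken = [False] * len(gts)
    tp_pairs: list[tuple[int, int]] = []
    fp: list[int] = []
    for i in order:
        best_j, best_v = -1, iou_thr
        for j in range(len(gts)):
            if gt_taken[j]:
                continue
            v = table.get((i, j), 0.0)
            if v > best_v:
                best_j, best_v = j, v
        if best_j >= 0:
            gt_taken[best_j] = True
            tp_pairs.append((i, best_j))
        else:
            fp.append(i)
    fn = [j for j, taken in enumerate(gt_taken) if not taken]
    return MatchResult(tp_pairs, fp, fn)


def precision_recall_f1(match: MatchResult, n_gt: int) -> tuple[float, float, float]:
    """precision = TP/(TP+FP); recall = TP/n_gt; F1 = harmonic mean.

    With zero predictions precision is undefined; it is reported as 1 (a
    warning is emitted) so the top of the curve stays well defined.
    """
    if n_gt <= 0:
        raise ValueError("n_gt must be positive")
    tp = match.n_tp
    n_pred = tp + len(match.fp)
    if n_pred == 0:
        warnings.warn("no predictions at this threshold; precision reported as 1")
        p = 1.0
    else:
        p = tp / n_pred
    r = tp / n_gt
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return p, r, f1


def pr_curve(
    preds: list[Detection],
    gts: list[Mask],
    n_bins: int = N_BINS,
    iou_thr: float = IOU_THRESHOLD,
) -> EvaluationCurve:
    """Precision-recall-F1 across equal-count score-bin thresholds.

    Scores are sorted ascending and split into ``n_bins`` bins whose sizes
    differ by at most one; each bin's maximum score is a threshold. When
    there are fewer distinct scores than bins, each distinct score is its
    own threshold. At threshold t the metrics are computed over predictions
    with score >= t (inclusive), so the top bin is never empty.
    """
    if not preds:
        raise ValueError("pr_curve needs at least one prediction")
    scores = np.sort(np.array([d.score for d in preds]))
    distinct = np.unique(scores)
    if len(distinct) < n_bins:
        thresholds = distinct
    else:
        thresholds = np.array([chunk[-1] for chunk in np.array_split(scores, n_bins)])
    table = _iou_table(preds, gts)
    ps, rs, f1s = [], [], []
    n_gt = len(gts)
    for t in thresholds:
        subset = [i for i, d in enumerate(preds) if d.score >= t]
        m = match_detections(preds, gts, iou_thr, _iou_cache=table, _pred_indices=subset)
        p, r, f1 = precision_recall_f1(m, n_gt)
        ps.append(p)
        rs.append(r)
        f1s.append(f1)
    curve = EvaluationCurve(
        thresholds=np.asarray(thresholds, dtype=float),
        precision=np.asarray(ps),
        recall=np.asarray(rs),
        f1=np.asarray(f1s),
    )
    curve.ap = average_precision(curve)
    return curve


def average_precision(curve: EvaluationCurve) -> float:
    """Trapezoidal area under the precision-recall curve.

    Points are sorted by recall, prepended with the (0, 1) extrapolation;
    the curve is not extended beyond the maximum realized recall.
    """
    if len(curve.recall) == 0:
        raise ValueError("empty curve")
    order = np.argsort(curve.recall, kind="stable")
    r = np.concatenate([[0.0], curve.recall[order]])
    p = np.concatenate([[1.0], curve.precision[order]])
    return float(np.trapezoid(p, r))


def best_threshold(curve: EvaluationCurve) -> tuple[float, float]:
    """The threshold maximizing F1; ties broken toward the smaller threshold."""
    if len(curve.thresholds) == 0:
        raise ValueError("empty curve")
    order = np.argsort(curve.thresholds, kind="stable")
    f1 = curve.f1[order]
    t = curve.thresholds[order]
    i = int(np.argmax(f1))  # argmax returns the first (smallest t) maximum
    return float(t[i]), float(f1[i])
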