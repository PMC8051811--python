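"""Object-level segmentation metrics at IoU thresholds.

Predicted and ground-truth instances are compared through their pixel
intersection over union (IoU). At a threshold ``t`` a one-to-one matching
is formed greedily over candidate pairs with IoU >= t in descending-IoU
order (ties broken by (gt_id, pred_id)); matched pairs are true positives,
unmatched predictions false positives, unmatched ground-truth instances
false negatives. At t >= 0.5 a pixel can support at most one pair above
threshold, so the greedy matching is the optimal one. Object-level true
negatives are undefined and carried as 0. From the counts:

    P(t)  = TP / (TP + FP)            (precision)
    R(t)  = TP / (TP + FN)            (recall)
    F1(t) = TP / (TP + (FP + FN)/2)

with the convention that a metric with an all-zero denominator is 0.
Mean IoU is reported in two conventions: over matched pairs only, and
over all ground-truth instances with unmatched ones contributing 0.
All metrics are invariant under relabelling of either map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import as_label_map

DEFAULT_THRESHOLDS = (0.50, 0.60, 0.70, 0.80, 0.90, 0.95)


@dataclass
class IoUMatrix:
    """Sparse IoU table over all overlapping (gt, pred) instance pairs."""

    pairs: pd.DataFrame  # columns: gt_id, pred_id, intersection_px, union_px, iou
    n_gt: int
    n_pred: int
    gt_ids: np.ndarray
    pred_ids: np.ndarray


@dataclass
class ConfusionCounts:
    """Confusion counts of the one-to-one matching at threshold ``t``."""

    t: float
    tp: int
    fp: int
    fn: int
    tn: int = 0  # object-level TN is undefined; carried as 0 by convention
    matches: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_gt(self) -> int:
        return self.tp + self.fn

    @property
    def n_pred(self) -> int:
        return self.tp + self.fp


@dataclass
class Metrics:
    precision: float
    recall: float
    f1: float
    mean_iou_matched: float
    mean_iou_all: float


def iou_matrix(gt: np.ndarray, pred: np.ndarray) -> IoUMatrix:
    """Exact pixel-count IoU for every overlapping instance pair."""
    gt = as_label_map(gt)
    pred = as_label_map(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"ground truth {gt.shape} and prediction {pred.shape} shapes differ")

    gt_ids, gt_areas = np.unique(gt[gt > 0], return_counts=True)
    pred_ids, pred_areas = np.unique(pred[pred > 0], return_counts=True)
    gt_area = dict(zip(gt_ids.tolist(), gt_areas.tolist()))
    pred_area = dict(zip(pred_ids.tolist(), pred_areas.tolist()))

    both = (gt > 0) & (pred > 0)
    if both.any():
        codes = np.stack([gt[both], pred[both]], axis=1)
        pairs_arr, inter = np.unique(codes, axis=0, return_counts=True)
        rows = []
        for (g, p), i in zip(pairs_arr.tolist(), inter.tolist()):
            union = gt_area[g] + pred_area[p] - i
            rows.append((int(g), int(p), int(i), int(union), i / union))
        pairs = pd.DataFrame(
            rows, columns=["gt_id", "pred_id", "intersection_px", "union_px", "iou"]
        )
    else:
        pairs = pd.DataFrame(
            columns=["gt_id", "pred_id", "intersection_px", "union_px", "iou"]
        ).astype({"gt_id": int, "pred_id": int, "intersection_px": int, "union_px": int, "iou": float})
    return IoUMatrix(
        pairs=pairs,
        n_gt=int(gt_ids.size),
        n_pred=int(pred_ids.size),
        gt_ids=gt_ids,
        pred_ids=pred_ids,
    )


def match_at_threshold(ioumat: IoUMatrix, t: float) -> ConfusionCounts:
    """Greedy one-to-one matching over pairs with IoU >= t."""
    if not 0 < t < 1:
        raise ValueError("IoU threshold must lie in (0, 1)")
    cand = ioumat.pairs[ioumat.pairs["iou"] >= t]
    cand = cand.sort_values(["iou", "gt_id", "pred_id"], ascending=[False, True, True])
    used_gt: set[int] = set()
    used_pred: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for row in cand.itertuples(index=False):
        if row.gt_id in used_gt or row.pred_id in used_pred:
            continue
        used_gt.add(row.gt_id)
        used_pred.add(row.pred_id)
        matches.append((int(row.gt_id), int(row.pred_id), float(row.iou)))
    tp = len(matches)
    return ConfusionCounts(
        t=t,
        tp=tp,
        fp=ioumat.n_pred - tp,
        fn=ioumat.n_gt - tp,
        matches=matches,
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def prf1(counts: ConfusionCounts) -> Metrics:
    """Precision, recall, F1 and the two mean-IoU conventions."""
    ious = [m[2] for m in counts.matches]
    return Metrics(
        precision=_safe_div(counts.tp, counts.tp + counts.fp),
        recall=_safe_div(counts.tp, counts.tp + counts.fn),
        f1=_safe_div(counts.tp, counts.tp + 0.5 * (counts.fp + counts.fn)),
        mean_iou_matched=float(np.mean(ious)) if ious else 0.0,
        mean_iou_all=_safe_div(float(np.sum(ious)), counts.n_gt),
    )


def evaluate_pair(gt: np.ndarray, pred: np.ndarray, t: float = 0.5) -> Metrics:
    """Convenience: IoU matrix + matching + metrics for one map pair."""
    return prf1(match_at_threshold(iou_matrix(gt, pred), t))


def f1_curve(
    gt: np.ndarray, pred: np.ndarray, thresholds=DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Metrics per IoU threshold (rows sorted by threshold)."""
    ioumat = iou_matrix(gt, pred)
    rows = []
    for t in sorted(thresholds):
        counts = match_at_threshold(ioumat, t)
        m = prf1(counts)
        rows.append(
            {
                "iou_threshold": t,
                "tp": counts.tp,
                "fp": counts.fp,
                "fn": counts.fn,
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
                "mean_iou_matched": m.mean_iou_matched,
                "mean_iou_all": m.mean_iou_all,
            }
        )
    return pd.DataFrame(rows)


def annotation_confusion(
    gt: np.ndarray,
    auto_labels: np.ndarray,
    kept: set[int] | None = None,
    restrict_to_kept: bool = False,
    t: float = 0.5,
) -> ConfusionCounts:
    """Confusion counts of an automatic annotation against ground truth.

    With ``restrict_to_kept``, ground-truth instances whose best-overlap
    automatic object was excluded by the area filter are dropped from the
    evaluation (they were knowingly not annotated); without it, every
    ground-truth instance counts. In both modes the prediction under
    evaluation contains only the kept objects (all objects when ``kept``
    is None).
    """
    gt = as_label_map(gt)
    auto_labels = as_label_map(auto_labels)
    if kept is None:
        kept = set(int(v) for v in np.unique(auto_labels) if v > 0)
    pred = np.where(np.isin(auto_labels, sorted(kept)), auto_labels, 0)

    gt_eval = gt
    if restrict_to_kept:
        full = iou_matrix(gt, auto_labels)
        drop: set[int] = set()
        if len(full.pairs):
            best = full.pairs.sort_values(
                ["iou", "pred_id"], ascending=[False, True]
            ).drop_duplicates("gt_id")
            drop = {int(r.gt_id) for r in best.itertuples(index=False) if int(r.pred_id) not in kept}
        # gt instances with no overlapping automatic object at all were
        # never detected, not filtered away: they stay in the evaluation
        if drop:
            gt_eval = np.where(np.isin(gt, sorted(drop)), 0, gt)
    return match_at_threshold(iou_matrix(gt_eval, pred), t)


def annotation_accuracy(
    gt: np.ndarray,
    auto_labels: np.ndarray,
    kept: set[int] | None = None,
    restrict_to_kept: bool = False,
    t: float = 0.5,
) -> Metrics:
    """Metrics over :func:`annotation_confusion` (see there for modes)."""
    return prf1(annotation_confusion(gt, auto_labels, kept, restrict_to_kept, t))
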