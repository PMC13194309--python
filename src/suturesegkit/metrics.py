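"""Frame-wise and segmental evaluation metrics, plus the paired
Wilcoxon signed-rank comparison.

Frame accuracy and macro-F1 score each frame independently; the segmental
edit score and overlap-F1 (F1@k) operate on the run-length segment form and
specifically penalize over-segmentation, which frame metrics barely see.
"""
from __future__ import annotations

from typing import Optional, Sequence

import edlib
import numpy as np
from scipy import stats
from sklearn.metrics import f1_score

from .types import (
    LabelSequence,
    MetricsReport,
    Segmentation,
    ValidationError,
)


# ------------------------------------------------------------- segmentation

def labels_to_segments(labels: LabelSequence) -> Segmentation:
    """Run-length encode a label sequence into half-open segments."""
    y = labels.labels
    boundaries = np.flatnonzero(np.diff(y)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(y)]))
    return Segmentation([(int(y[s]), int(s), int(e)) for s, e in zip(starts, ends)])


def segments_to_labels(seg: Segmentation, vocabulary=None, fps: float = 30.0
                       ) -> LabelSequence:
    """Inverse of :func:`labels_to_segments`."""
    y = np.empty(seg.n_frames, dtype=np.int64)
    for cls, s, e in seg.segments:
        y[s:e] = cls
    if vocabulary is None:
        n = max(c for c, _, _ in seg.segments) + 1
        vocabulary = tuple(f"class_{i}" for i in range(n))
    return LabelSequence(y, vocabulary, fps)


def _check_paired(pred: LabelSequence, gt: LabelSequence) -> None:
    if len(pred) != len(gt):
        raise ValidationError(f"length mismatch: pred {len(pred)} vs gt {len(gt)}")


# ------------------------------------------------------------ frame metrics

def frame_accuracy(pred: LabelSequence, gt: LabelSequence) -> float:
    """Percent of frames with matching labels."""
    _check_paired(pred, gt)
    return float(100.0 * np.mean(pred.labels == gt.labels))


def f1_macro_framewise(pred: LabelSequence, gt: LabelSequence) -> float:
    """Macro-averaged frame-wise F1 over the classes occurring in gt or pred.

    A class absent from both is excluded; within an occurring class a
    zero-division (no predicted or no true frames) counts as F1 = 0.
    """
    _check_paired(pred, gt)
    present = sorted(set(gt.labels.tolist()) | set(pred.labels.tolist()))
    return float(100.0 * f1_score(gt.labels, pred.labels, labels=present,
                                  average="macro", zero_division=0))


# --------------------------------------------------------- segmental metrics

def _class_string(labels: LabelSequence) -> str:
    return "".join(chr(65 + c) for c in labels_to_segments(labels).class_sequence())


def edit_score(pred: LabelSequence, gt: LabelSequence) -> float:
    """Segmental edit score: 100 * (1 - Levenshtein / max segment count).

    The Levenshtein distance is taken between the class strings of the two
    segmentations, so repeated insertions (over-segmentation) are punished.
    """
    _check_paired(pred, gt)
    a, b = _class_string(pred), _class_string(gt)
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return float(max(0.0, 100.0 * (1.0 - dist / max(len(a), len(b)))))


def _interval_iou(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union > 0 else 0.0


def f1_at_k(pred: LabelSequence, gt: LabelSequence, k: float) -> float:
    """Overlap F1 at IoU threshold ``k`` with greedy temporal-order matching.

    Each predicted segment (in temporal order) is matched to the unmatched
    same-class ground-truth segment of maximal IoU; it is a true positive if
    that IoU reaches ``k``, otherwise a false positive.  Ground-truth
    segments left unmatched are false negatives.
    """
    if not (0.0 < k <= 1.0):
        raise ValidationError(f"IoU threshold must lie in (0, 1], got {k}")
    _check_paired(pred, gt)
    pred_segs = labels_to_segments(pred).segments
    gt_segs = labels_to_segments(gt).segments
    matched = [False] * len(gt_segs)
    tp = fp = 0
    for p_cls, p_s, p_e in pred_segs:
        best_iou, best_j = 0.0, -1
        for j, (g_cls, g_s, g_e) in enumerate(gt_segs):
            if matched[j] or g_cls != p_cls:
                continue
            iou = _interval_iou((p_s, p_e), (g_s, g_e))
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= k:
            tp += 1
            matched[best_j] = True
        else:
            fp += 1
    fn = matched.count(False)
    denom = 2 * tp + fp + fn
    return float(100.0 * 2 * tp / denom) if denom else 100.0


def compute_report(pred: LabelSequence, gt: LabelSequence) -> MetricsReport:
    """All six metrics for one prediction/ground-truth pair."""
    return MetricsReport(
        accuracy=frame_accuracy(pred, gt),
        edit=edit_score(pred, gt),
        f1_macro=f1_macro_framewise(pred, gt),
        f1_at_10=f1_at_k(pred, gt, 0.10),
        f1_at_25=f1_at_k(pred, gt, 0.25),
        f1_at_50=f1_at_k(pred, gt, 0.50),
    )


# ------------------------------------------------------------------ Wilcoxon

def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float],
                         alternative: str = "greater") -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test of x against y.

    Zero differences are dropped; |differences| are midranked.  The exact
    null distribution is used for n <= 20 without ties, the tie-corrected
    normal approximation otherwise.  ``alternative='greater'`` tests that x
    tends to exceed y.  Returns (statistic, p-value).
    """
    if alternative not in ("greater", "two_sided", "two-sided", "less"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    alt = "two-sided" if alternative == "two_sided" else alternative
    d = np.asarray(x, dtype=np.float64) - np.asarray(y, dtype=np.float64)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValidationError("all differences zero: test undefined")
    has_ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= 20 and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative=alt, method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------- aggregation

def aggregate_folds(per_fold: Sequence[MetricsReport], ddof: int = 1) -> dict:
    """Mean and standard deviation of each metric across cross-validation folds.

    ``ddof=1`` (sample std) by default; a single fold reports std 0.
    """
    if not per_fold:
        raise ValidationError("need at least one fold")
    out = {}
    for name in MetricsReport.METRIC_FIELDS:
        vals = np.array([getattr(r, name) for r in per_fold], dtype=np.float64)
        std = float(np.std(vals, ddof=ddof)) if len(vals) > ddof else 0.0
        out[name] = {"mean": float(vals.mean()), "std": std,
                     "per_fold": vals.tolist()}
    return out


__all__ = [
    "labels_to_segments", "segments_to_labels",
    "frame_accuracy", "f1_macro_framewise", "edit_score", "f1_at_k",
    "compute_report", "wilcoxon_signed_rank", "aggregate_folds",
]
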