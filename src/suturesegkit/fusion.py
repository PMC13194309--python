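"""Combining modalities: feature concatenation, logit averaging,
prediction smoothing, and logit-norm confidence binning.

The ensemble averages *logits* rather than softmax probabilities: confident
models produce logits of larger norm, so they dominate the average instead
of being flattened by the softmax.  The binning utilities quantify that
confidence-accuracy relationship and where the ensemble helps.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .types import (
    DEFAULT_FPS,
    DEFAULT_VOCABULARY,
    FeatureSequence,
    LabelSequence,
    LogitSequence,
    ValidationError,
)


def concat_modalities(seqs: Sequence[FeatureSequence]) -> FeatureSequence:
    """Concatenate per-frame feature vectors; column order follows input order."""
    if not seqs:
        raise ValidationError("need at least one feature sequence")
    T, stride = seqs[0].n_frames, seqs[0].stride
    for s in seqs[1:]:
        if s.n_frames != T:
            raise ValidationError(f"length mismatch: {s.n_frames} != {T}")
        if s.stride != stride:
            raise ValidationError(f"stride mismatch: {s.stride} != {stride}")
    if len(seqs) == 1:
        return seqs[0]
    return FeatureSequence(np.hstack([s.values for s in seqs]), "concat", stride)


def average_logits(runs: Sequence[LogitSequence]) -> LogitSequence:
    """Element-wise arithmetic mean of logit sequences (order-invariant)."""
    if not runs:
        raise ValidationError("need at least one logit sequence")
    shape = runs[0].values.shape
    for r in runs[1:]:
        if r.values.shape != shape:
            raise ValidationError(f"shape mismatch: {r.values.shape} != {shape}")
    return LogitSequence(np.mean([r.values for r in runs], axis=0), runs[0].stride)


def _runs_of(labels: np.ndarray) -> list[tuple[int, int, int]]:
    out = []
    start = 0
    for t in range(1, len(labels) + 1):
        if t == len(labels) or labels[t] != labels[t - 1]:
            out.append((int(labels[start]), start, t))
            start = t
    return out


def smooth_predictions(labels: LabelSequence, min_run: int = 3) -> LabelSequence:
    """Absorb short interior runs into their neighbors.

    Every maximal run shorter than ``min_run`` — excluding runs touching
    either end of the sequence, which lack a two-sided neighborhood — is
    replaced by the label of the longer adjacent run (tie broken toward the
    left neighbor).  Applied iteratively until no interior run is short.
    """
    if min_run < 1:
        raise ValidationError("min_run must be >= 1")
    out = labels.labels.copy()
    T = len(out)
    while True:
        runs = _runs_of(out)
        changed = False
        for i, (cls, s, e) in enumerate(runs):
            if s == 0 or e == T or (e - s) >= min_run:
                continue
            left, right = runs[i - 1], runs[i + 1]
            left_len = left[2] - left[1]
            right_len = right[2] - right[1]
            winner = left[0] if left_len >= right_len else right[0]
            out[s:e] = winner
            changed = True
            break  # run boundaries changed; recompute
        if not changed:
            return LabelSequence(out, labels.vocabulary, labels.fps)


def _equal_size_bins(n: int, n_bins: int) -> list[int]:
    """Bin sizes differing by at most one; the remainder goes to the lowest bins."""
    base, rem = divmod(n, n_bins)
    return [base + 1 if i < rem else base for i in range(n_bins)]


def logit_norm_accuracy_bins(logits: LogitSequence, labels: LabelSequence,
                             n_bins: int = 10) -> list[dict]:
    """Frame accuracy grouped by logit-norm quantile bin.

    Frames are sorted by the Euclidean norm of their logit vector and split
    into ``n_bins`` contiguous near-equal groups (lowest norms first); each
    bin reports its mean norm, frame accuracy (percent) and frame count.
    """
    T = logits.n_frames
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    if n_bins > T:
        raise ValidationError(f"n_bins={n_bins} exceeds frame count T={T}")
    if len(labels) != T:
        raise ValidationError("logits and labels must share length")
    norms = np.linalg.norm(logits.values, axis=1)
    order = np.argsort(norms, kind="stable")
    correct = (np.argmax(logits.values, axis=1) == labels.labels)
    bins = []
    off = 0
    for size in _equal_size_bins(T, n_bins):
        idx = order[off:off + size]
        bins.append({
            "mean_norm": float(norms[idx].mean()),
            "accuracy": float(100.0 * correct[idx].mean()),
            "count": int(size),
        })
        off += size
    return bins


def ensemble_delta_bins(logits_a: LogitSequence, logits_b: LogitSequence,
                        labels: LabelSequence, n_bins: int = 10) -> list[dict]:
    """Per-bin accuracy difference accuracy(b) - accuracy(a), with bins
    defined by the norms of the reference run ``logits_a``."""
    T = logits_a.n_frames
    if logits_b.n_frames != T or len(labels) != T:
        raise ValidationError("all inputs must share length")
    if n_bins < 1 or n_bins > T:
        raise ValidationError("n_bins must lie in [1, T]")
    norms = np.linalg.norm(logits_a.values, axis=1)
    order = np.argsort(norms, kind="stable")
    correct_a = (np.argmax(logits_a.values, axis=1) == labels.labels)
    correct_b = (np.argmax(logits_b.values, axis=1) == labels.labels)
    bins = []
    off = 0
    for size in _equal_size_bins(T, n_bins):
        idx = order[off:off + size]
        bins.append({
            "mean_norm": float(norms[idx].mean()),
            "delta_accuracy": float(100.0 * (correct_b[idx].mean()
                                             - correct_a[idx].mean())),
            "count": int(size),
        })
        off += size
    return bins


def ensemble_predictions(runs: Sequence[LogitSequence], min_run: int = 3,
                         vocabulary=DEFAULT_VOCABULARY,
                         fps: float = DEFAULT_FPS) -> LabelSequence:
    """Average logits across runs, take the frame argmax (ties toward the
    lowest class index), then absorb short interior runs."""
    avg = average_logits(runs)
    return smooth_predictions(avg.argmax_labels(vocabulary, fps), min_run)


__all__ = [
    "concat_modalities", "average_logits", "smooth_predictions",
    "logit_norm_accuracy_bins", "ensemble_delta_bins", "ensemble_predictions",
]
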