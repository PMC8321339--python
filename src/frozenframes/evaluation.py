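"""Evaluation protocol: correctness criterion, K-sweep, frame-level ROC/AUC.

A detected minimum counts as a correct frozen-frame detection when its
distance from the annotated event onset *or* offset is strictly less than
``N/2``, with ``N`` the maximal expected micro-expression length at the
clip's frame rate.  Aggregate quality is reported two ways: the percentage
of sequences with a correct detection among the ``K`` smallest-sigma minima
(swept over K), and a pooled frame-level ROC built by growing K, where the
predicted-positive frames are size-``N`` windows centered on the selected
minima and the ground-truth-positive frames are the closed
``[onset, offset]`` interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .video_io import MEAnnotation

__all__ = [
    "EvalConfig",
    "EvalResult",
    "default_N",
    "is_correct",
    "k_sweep",
    "roc_auc",
]

logger = logging.getLogger(__name__)

DEFAULT_K_VALUES = (1, 2, 3, 5, 8, 10)


def default_N(fps: float) -> int:
    """Maximal expected micro-expression length (frames) at frame rate ``fps``.

    MEs last up to about 0.32 s, so ``N = round(0.32 * fps)``: 64 frames at
    200 fps, 8 frames at 25 fps.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    return int(math.floor(0.32 * fps + 0.5))


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation settings: event length N and the K values to sweep."""

    N: int
    K_values: tuple[int, ...] = DEFAULT_K_VALUES

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not self.K_values or any(k < 1 for k in self.K_values):
            raise ValueError("K_values must be non-empty positive integers")


@dataclass
class EvalResult:
    """Per-K frame-level counts, rates and the trapezoid AUC."""

    table: pd.DataFrame  # columns K, TP, FP, TN, FN, TPR, FPR
    auc: float
    n_sequences: int = 0
    skipped: list[str] = field(default_factory=list)


def is_correct(minimum: int, ann: MEAnnotation) -> bool:
    """True iff the minimum lies strictly within N/2 frames of onset or offset."""
    distance = min(abs(minimum - ann.onset), abs(minimum - ann.offset))
    return distance < ann.N / 2.0


def k_sweep(
    per_sequence_minima: Mapping[str, Sequence[int]],
    annotations: Sequence[MEAnnotation],
    K_values: Sequence[int] = DEFAULT_K_VALUES,
) -> pd.DataFrame:
    """Percentage of sequences correctly handled by the K smallest-sigma minima.

    ``per_sequence_minima`` maps sequence id to its selected minima sorted by
    ascending sigma value (so the first K entries are the K smallest).
    Returns a frame with columns ``K``, ``count``, ``total``, ``percentage``
    (two decimals).
    """
    if not K_values:
        raise ValueError("K_values must be non-empty")
    by_id = {ann.sequence_id: ann for ann in annotations}
    rows = []
    for K in K_values:
        count = 0
        total = 0
        for seq_id, minima in per_sequence_minima.items():
            ann = by_id.get(seq_id)
            if ann is None:
                logger.warning("no annotation for sequence %s; skipped", seq_id)
                continue
            total += 1
            if any(is_correct(t, ann) for t in list(minima)[:K]):
                count += 1
        pct = round(100.0 * count / total, 2) if total else 0.0
        rows.append((K, count, total, pct))
    return pd.DataFrame(rows, columns=["K", "count", "total", "percentage"])


def _prediction_mask(minima: Sequence[int], N: int, clip_length: int) -> np.ndarray:
    """Union of size-N windows [t - floor(N/2), t + floor(N/2) - 1], clipped."""
    mask = np.zeros(clip_length, dtype=bool)
    half = N // 2
    for t in minima:
        a = max(1, t - half)
        b = min(clip_length, t + half - 1 + (N % 2))
        mask[a - 1 : b] = True
    return mask


def roc_auc(
    per_sequence_minima: Mapping[str, Sequence[int]],
    annotations: Sequence[MEAnnotation],
    N: int,
    clip_lengths: Mapping[str, int],
    truth_intervals: Optional[Mapping[str, Sequence[tuple[int, int]]]] = None,
) -> EvalResult:
    """Pooled frame-level ROC over growing K, with trapezoid AUC.

    For each K, the predicted-positive frames of a sequence are the union of
    size-``N`` windows centered at its K smallest-sigma minima; ground-truth
    positives are the closed ``[onset, offset]`` interval (or, for clips
    with several events, the union of the intervals in ``truth_intervals``).
    TP/FP/TN/FN are pooled over sequences; the curve is anchored at (0, 0)
    and (1, 1).  Sequences without an annotation or clip length are skipped
    with a warning.
    """
    by_id = {ann.sequence_id: ann for ann in annotations}
    usable: list[tuple[str, Sequence[int], MEAnnotation, int]] = []
    skipped: list[str] = []
    for seq_id, minima in per_sequence_minima.items():
        ann = by_id.get(seq_id)
        length = clip_lengths.get(seq_id)
        if ann is None or length is None:
            logger.warning("sequence %s missing annotation or length; skipped", seq_id)
            skipped.append(seq_id)
            continue
        usable.append((seq_id, list(minima), ann, int(length)))
    if not usable:
        raise ValueError("no sequence has both an annotation and a clip length")

    truth_masks = []
    for seq_id, _, ann, length in usable:
        truth = np.zeros(length, dtype=bool)
        intervals = (
            truth_intervals.get(seq_id, [(ann.onset, ann.offset)])
            if truth_intervals is not None
            else [(ann.onset, ann.offset)]
        )
        for onset, offset in intervals:
            truth[max(1, onset) - 1 : min(length, offset)] = True
        truth_masks.append(truth)

    max_k = max((len(m) for _, m, _, _ in usable), default=0)
    rows = []
    for K in range(0, max_k + 1):
        tp = fp = tn = fn = 0
        for (_, minima, ann, length), truth in zip(usable, truth_masks):
            pred = _prediction_mask(minima[:K], ann.N if N is None else N, length)
            tp += int(np.sum(pred & truth))
            fp += int(np.sum(pred & ~truth))
            fn += int(np.sum(~pred & truth))
            tn += int(np.sum(~pred & ~truth))
        tpr = tp / (tp + fn) if tp + fn else 0.0
        fpr = fp / (fp + tn) if fp + tn else 0.0
        rows.append((K, tp, fp, tn, fn, tpr, fpr))

    table = pd.DataFrame(rows, columns=["K", "TP", "FP", "TN", "FN", "TPR", "FPR"])
    fpr = np.concatenate([[0.0], table["FPR"].to_numpy(), [1.0]])
    tpr = np.concatenate([[0.0], table["TPR"].to_numpy(), [1.0]])
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return EvalResult(table=table, auc=auc, n_sequences=len(usable), skipped=skipped)
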