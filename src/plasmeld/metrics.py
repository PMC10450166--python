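"""Classification metrics: precision/recall/F1 and the PR curve."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "prf1", "pr_curve", "confusion"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion(predicted: list[bool], truth: list[bool]) -> ConfusionCounts:
    tp = sum(p and t for p, t in zip(predicted, truth))
    fp = sum(p and not t for p, t in zip(predicted, truth))
    tn = sum(not p and not t for p, t in zip(predicted, truth))
    fn = sum(not p and t for p, t in zip(predicted, truth))
    return ConfusionCounts(tp, fp, tn, fn)


def prf1(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, recall, F1); zero where a denominator vanishes."""
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return precision, recall, f1


def pr_curve(scores: list[tuple[float, bool]]) -> tuple[list[tuple[float, float, float]], float]:
    """Precision-recall curve and its area.

    Sweeps thresholds over the unique scores (ties grouped), returning
    points as (threshold, recall, precision) with recall non-decreasing,
    and the trapezoidal area over recall. Raises if only one class is
    present in the truth labels.
    """
    if not scores:
        raise ValueError("empty score list")
    y = np.array([t for _, t in scores], dtype=bool)
    s = np.array([p for p, _ in scores], dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("pr_curve requires both classes in the truth labels")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp_cum = np.cumsum(y_sorted)
    n_cum = np.arange(1, len(y) + 1)
    # keep the last index of each tied-score group
    last = np.nonzero(np.diff(s_sorted, append=np.nan))[0]
    points = []
    prev_recall = 0.0
    prev_precision = 1.0
    area = 0.0
    for i in last:
        recall = tp_cum[i] / n_pos
        precision = tp_cum[i] / n_cum[i]
        area += (recall - prev_recall) * (precision + prev_precision) / 2.0
        points.append((float(s_sorted[i]), float(recall), float(precision)))
        prev_recall, prev_precision = recall, precision
    return points, float(area)
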