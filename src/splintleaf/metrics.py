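"""Segmentation evaluation: pixel confusion counts and the derived metrics
(per-class IoU, mIoU, pixel accuracy, mPA, mPrecision, recall).

The leaf is the positive class.  Per-class IoU is TP/(TP+FP+FN) with the
roles of the counts swapped for the background class; mIoU is the mean of
the two.  mPA is the mean per-class pixel accuracy and is reported
separately from the overall pixel accuracy (TP+TN)/total.  Recall defaults
to the standard TP/(TP+FN); a published variant with TP+TN in the
denominator is available behind ``printed_recall_variant`` for
compatibility with that (almost certainly typographical) form.

When a class is absent from both prediction and truth its undefined ratios
are scored 1 (perfect agreement on absence) and flagged in the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies with leaf as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass(frozen=True)
class MetricsReport:
    miou: float
    pixel_accuracy: float
    mean_pixel_accuracy: float
    mean_precision: float
    recall: float
    per_class_iou: tuple[float, float]   # (leaf, background)
    absent_class_flagged: bool = False
    inference_seconds_per_image: float | None = None   # informational only


def confusion(pred_mask: np.ndarray, true_mask: np.ndarray) -> ConfusionCounts:
    """Per-pixel confusion counts between two equal-shape binary masks."""
    p = np.asarray(pred_mask)
    t = np.asarray(true_mask)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    p = p != 0
    t = t != 0
    tp = int(np.logical_and(p, t).sum())
    fp = int(np.logical_and(p, ~t).sum())
    fn = int(np.logical_and(~p, t).sum())
    tn = int(np.logical_and(~p, ~t).sum())
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int, absent: bool) -> float:
    if den == 0:
        return 1.0 if absent else 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts,
                    printed_recall_variant: bool = False,
                    inference_seconds_per_image: float | None = None
                    ) -> MetricsReport:
    """Derive the full metric report from aggregated confusion counts."""
    c = counts
    if c.total == 0:
        raise ValueError("confusion counts are empty")
    leaf_absent = (c.tp + c.fn + c.fp) == 0   # no leaf in truth or prediction
    bg_absent = (c.tn + c.fn + c.fp) == 0
    iou_leaf = _ratio(c.tp, c.tp + c.fp + c.fn, leaf_absent)
    iou_bg = _ratio(c.tn, c.tn + c.fn + c.fp, bg_absent)
    acc_leaf = _ratio(c.tp, c.tp + c.fn, (c.tp + c.fn) == 0)
    acc_bg = _ratio(c.tn, c.tn + c.fp, (c.tn + c.fp) == 0)
    prec_leaf = _ratio(c.tp, c.tp + c.fp, (c.tp + c.fp) == 0)
    prec_bg = _ratio(c.tn, c.tn + c.fn, (c.tn + c.fn) == 0)
    if printed_recall_variant:
        recall = _ratio(c.tp, c.tp + c.tn, (c.tp + c.tn) == 0)
    else:
        recall = _ratio(c.tp, c.tp + c.fn, (c.tp + c.fn) == 0)
    return MetricsReport(
        miou=(iou_leaf + iou_bg) / 2.0,
        pixel_accuracy=(c.tp + c.tn) / c.total,
        mean_pixel_accuracy=(acc_leaf + acc_bg) / 2.0,
        mean_precision=(prec_leaf + prec_bg) / 2.0,
        recall=recall,
        per_class_iou=(iou_leaf, iou_bg),
        absent_class_flagged=leaf_absent or bg_absent,
        inference_seconds_per_image=inference_seconds_per_image,
    )
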