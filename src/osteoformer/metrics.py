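"""Pixel-overlap evaluation: confusion counts, IoU and Dice.

IoU = TP / (TP + FP + FN) and DSC = 2 TP / (2 TP + FP + FN), computed from
per-image pixel confusion counts for the foreground class.  The two scores
satisfy DSC = 2 IoU / (1 + IoU) per image, which is why Dice always reads
higher than IoU on the same segmentation.  When both masks are empty the
score is defined as 1 (a correct prediction of absence).

Aggregation over an image set defaults to the arithmetic mean of per-image
scores; ``pooled=True`` instead sums confusion counts over all images
before applying the formulas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricScores",
    "EvaluationResult",
    "confusion_counts",
    "iou",
    "dsc",
    "evaluate_set",
]


@dataclass(frozen=True)
class ConfusionCounts:
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


@dataclass(frozen=True)
class MetricScores:
    iou: float
    dsc: float


@dataclass
class EvaluationResult:
    per_image: list[MetricScores]
    mean_iou: float
    mean_dsc: float
    n: int

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "image_id": range(self.n),
            "iou": [s.iou for s in self.per_image],
            "dsc": [s.dsc for s in self.per_image],
        }).to_csv(path, index=False)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"mean_iou": self.mean_iou, "mean_dsc": self.mean_dsc, "n": self.n},
            indent=2))


def _as_binary(arr, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return arr.astype(bool)


def confusion_counts(pred, gt) -> ConfusionCounts:
    """Pixel-wise TP/FP/FN/TN for two equal-shape binary masks."""
    p = _as_binary(pred, "pred")
    g = _as_binary(gt, "gt")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=p.size - tp - fp - fn)


def iou(counts: ConfusionCounts) -> float:
    """Intersection over union; 1.0 when both masks are empty."""
    denom = counts.tp + counts.fp + counts.fn
    return 1.0 if denom == 0 else counts.tp / denom


def dsc(counts: ConfusionCounts) -> float:
    """Dice similarity coefficient; 1.0 when both masks are empty."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    return 1.0 if denom == 0 else 2 * counts.tp / denom


def evaluate_set(predictions, gts, pooled: bool = False) -> EvaluationResult:
    """Score a list of predicted masks against ground truths."""
    if len(predictions) != len(gts):
        raise ValueError(
            f"{len(predictions)} predictions vs {len(gts)} ground truths")
    counts = [confusion_counts(p, g) for p, g in zip(predictions, gts)]
    per_image = [MetricScores(iou=iou(c), dsc=dsc(c)) for c in counts]
    if pooled:
        total = ConfusionCounts(tp=sum(c.tp for c in counts),
                                fp=sum(c.fp for c in counts),
                                fn=sum(c.fn for c in counts),
                                tn=sum(c.tn for c in counts))
        mean_iou, mean_dsc = iou(total), dsc(total)
    else:
        mean_iou = float(np.mean([s.iou for s in per_image])) if per_image else 1.0
        mean_dsc = float(np.mean([s.dsc for s in per_image])) if per_image else 1.0
    return EvaluationResult(per_image=per_image, mean_iou=mean_iou,
                            mean_dsc=mean_dsc, n=len(per_image))
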