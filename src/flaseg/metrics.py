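"""Hard-mask evaluation metrics (MIoU, ACC, Dice) on an explicit
confusion-count core, with macro (per-image mean) and micro (pooled pixels)
aggregation and CSV/JSON report writers.  All metrics are percentages."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel tallies with label 1 (FAZ) as the positive class."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    for name, arr in (("pred", pred), ("truth", truth)):
        bad = np.setdiff1d(np.unique(arr), [0, 1])
        if bad.size:
            raise ValueError(f"{name} contains labels outside {{0, 1}}: {bad.tolist()}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def _iou(inter: int, union: int) -> float:
    # class absent from both masks: IoU 1 by convention
    return 1.0 if union == 0 else inter / union


def miou(counts: ConfusionCounts) -> float:
    """Mean of the two per-class IoUs, as a percentage."""
    if counts.total == 0:
        raise ValueError("cannot compute MIoU of an empty batch")
    iou_pos = _iou(counts.tp, counts.tp + counts.fp + counts.fn)
    iou_neg = _iou(counts.tn, counts.tn + counts.fn + counts.fp)
    return 100.0 * 0.5 * (iou_pos + iou_neg)


def acc(counts: ConfusionCounts) -> float:
    """(TP + TN) / total, as a percentage."""
    if counts.total == 0:
        raise ValueError("cannot compute ACC of an empty batch")
    return 100.0 * (counts.tp + counts.tn) / counts.total


def dice_coef(counts: ConfusionCounts) -> float:
    """2 TP / (2 TP + FP + FN), as a percentage; 100 if both masks are empty."""
    den = 2 * counts.tp + counts.fp + counts.fn
    return 100.0 if den == 0 else 100.0 * 2 * counts.tp / den


@dataclass
class MetricReport:
    """Macro = mean of per-image metrics; micro = metrics of pooled pixels."""

    macro: dict[str, float]
    micro: dict[str, float]
    per_image: list[dict[str, float]] = field(default_factory=list)
    aggregation: str = "macro"  # which block the shorthand properties expose

    @property
    def miou(self) -> float:
        return getattr(self, self.aggregation)["miou"]

    @property
    def acc(self) -> float:
        return getattr(self, self.aggregation)["acc"]

    @property
    def dice(self) -> float:
        return getattr(self, self.aggregation)["dice"]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "aggregation": self.aggregation, "macro": self.macro,
            "micro": self.micro, "per_image": self.per_image}, indent=2))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["image", "miou", "acc", "dice"])
            for i, row in enumerate(self.per_image):
                w.writerow([row.get("name", i), f"{row['miou']:.4f}",
                            f"{row['acc']:.4f}", f"{row['dice']:.4f}"])
            w.writerow(["macro", f"{self.macro['miou']:.4f}",
                        f"{self.macro['acc']:.4f}", f"{self.macro['dice']:.4f}"])
            w.writerow(["micro", f"{self.micro['miou']:.4f}",
                        f"{self.micro['acc']:.4f}", f"{self.micro['dice']:.4f}"])


def _triple(counts: ConfusionCounts) -> dict[str, float]:
    return {"miou": miou(counts), "acc": acc(counts), "dice": dice_coef(counts)}


def evaluate_masks(preds, truths, names=None) -> MetricReport:
    """Per-image + macro + micro metrics for matched mask sequences."""
    preds = list(preds)
    truths = list(truths)
    if len(preds) != len(truths) or not preds:
        raise ValueError("need equal, nonzero numbers of predicted and truth masks")
    per_image = []
    pooled = np.zeros(4, dtype=np.int64)
    for i, (p, t) in enumerate(zip(preds, truths)):
        c = confusion(p, t)
        row = _triple(c)
        row["name"] = str(names[i]) if names is not None else str(i)
        per_image.append(row)
        pooled += [c.tp, c.tn, c.fp, c.fn]
    micro = _triple(ConfusionCounts(*[int(v) for v in pooled]))
    macro = {k: float(np.mean([r[k] for r in per_image])) for k in ("miou", "acc", "dice")}
    return MetricReport(macro=macro, micro=micro, per_image=per_image)
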