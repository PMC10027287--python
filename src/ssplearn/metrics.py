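"""Binary classification metrics: ACC, SP, SE and MCC.

ACC = (TP+TN)/n, SP = TN/(TN+FP), SE = TP/(TP+FN) and the Matthews
correlation coefficient MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FN)(TN+FP)),
with 0 returned whenever a denominator factor vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricReport:
    ACC: float
    SP: float
    SE: float
    MCC: float

    def to_dict(self) -> dict:
        return {"ACC": self.ACC, "SP": self.SP, "SE": self.SE, "MCC": self.MCC}


def confusion(labels, predictions) -> ConfusionCounts:
    """Exact TP/FP/TN/FN counts from 0/1 labels and predictions."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape:
        raise ValueError(
            f"labels and predictions differ in length: {labels.shape} vs {predictions.shape}")
    if labels.size == 0:
        raise ValueError("empty inputs")
    for arr, what in ((labels, "labels"), (predictions, "predictions")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{what} must be 0/1")
    return ConfusionCounts(
        TP=int(np.sum((labels == 1) & (predictions == 1))),
        FP=int(np.sum((labels == 0) & (predictions == 1))),
        TN=int(np.sum((labels == 0) & (predictions == 0))),
        FN=int(np.sum((labels == 1) & (predictions == 0))),
    )


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    if c.total == 0:
        raise ValueError("empty confusion table")
    tp, fp, tn, fn = float(c.TP), float(c.FP), float(c.TN), float(c.FN)
    acc = (tp + tn) / c.total
    sp = tn / (tn + fp) if (tn + fp) > 0 else 0.0
    se = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fn) * (tn + fp)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return MetricReport(ACC=acc, SP=sp, SE=se, MCC=float(mcc))


def evaluate(labels, predictions) -> MetricReport:
    """Convenience composition of `confusion` and `compute_metrics`."""
    return compute_metrics(confusion(labels, predictions))
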