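"""Confusion counts and precision / recall / F1 for binary triage.

Positive (relevant) is class 1.  P = TP/(TP+FP), R = TP/(TP+FN),
F1 = 2PR/(P+R); any metric whose denominator is zero is reported as 0.
Metrics are kept at full precision internally and conventionally printed at
three decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "TN": self.tn,
            "P": self.precision,
            "R": self.recall,
            "F1": self.f1,
        }

    def confusion_text(self) -> str:
        """Text confusion matrix (rows: actual, columns: predicted)."""
        return (
            "              Predict\n"
            "Actual      True   False\n"
            f"True    {self.tp:8d}{self.fn:8d}\n"
            f"False   {self.fp:8d}{self.tn:8d}\n"
        )


def confusion_counts(gold, pred) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) with positive = 1."""
    gold = np.asarray(gold, dtype=np.int64)
    pred = np.asarray(pred, dtype=np.int64)
    if gold.shape != pred.shape:
        raise ValueError(f"length mismatch: gold {gold.shape}, pred {pred.shape}")
    bad = set(np.unique(np.concatenate([gold, pred]))) - {0, 1} if gold.size else set()
    if bad:
        raise ValueError(f"labels must be binary 0/1; got extra values {sorted(bad)}")
    tp = int(np.sum((gold == 1) & (pred == 1)))
    fp = int(np.sum((gold == 0) & (pred == 1)))
    fn = int(np.sum((gold == 1) & (pred == 0)))
    tn = int(np.sum((gold == 0) & (pred == 0)))
    return tp, fp, fn, tn


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(P, R, F1) from counts, with the zero-denominator convention."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r, f1_from_pr(p, r)


def f1_from_pr(p: float, r: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if not (0.0 <= p <= 1.0 and 0.0 <= r <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if p + r == 0.0:
        return 0.0
    return 2.0 * p * r / (p + r)


def evaluate(gold, pred) -> EvalResult:
    """Full evaluation record from gold and predicted 0/1 label vectors."""
    tp, fp, fn, tn = confusion_counts(gold, pred)
    p, r, f1 = precision_recall_f1(tp, fp, fn)
    return EvalResult(tp=tp, fp=fp, fn=fn, tn=tn, precision=p, recall=r, f1=f1)
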