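"""Evaluation metrics: per-class P/R/F1, micro-F1, sensitivity/specificity,
ever-smoker merging, and 2x2 extraction evaluation.

Rates with an empty denominator are reported as ``None`` (absent), never 0:
a class with gold members but no correct predictions scores 0, while a class
absent from the gold altogether has no defined recall.  Sensitivity is, by
definition, the same quantity as recall; specificity is the one-vs-rest
true-negative rate.  In single-label multiclass classification the micro-F1
equals overall accuracy (pooled TP = pooled correct, pooled FP = pooled FN),
which the tests assert against an independent trace/total oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .corpus import SMOKER_STATUSES, STATUS_ORDER, SmokingStatus


@dataclass(frozen=True)
class ConfusionMatrix:
    """Gold x predicted counts over an ordered class list."""

    classes: tuple[SmokingStatus, ...]
    counts: np.ndarray  # shape (n_classes, n_classes), gold rows

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        n = len(self.classes)
        if counts.shape != (n, n):
            raise ValueError(f"counts shape {counts.shape} != ({n}, {n})")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @classmethod
    def from_pairs(
        cls,
        gold: Sequence[SmokingStatus],
        predicted: Sequence[SmokingStatus],
        classes: tuple[SmokingStatus, ...] = STATUS_ORDER,
    ) -> "ConfusionMatrix":
        if len(gold) != len(predicted):
            raise ValueError("gold and predicted must have equal length")
        idx = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for g, p in zip(gold, predicted):
            counts[idx[g], idx[p]] += 1
        return cls(classes=classes, counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def gold_sizes(self) -> dict[SmokingStatus, int]:
        return {c: int(self.counts[i].sum()) for i, c in enumerate(self.classes)}

    def to_dict(self) -> dict:
        return {
            "classes": [c.value for c in self.classes],
            "counts": self.counts.tolist(),
        }


@dataclass(frozen=True)
class TwoByTwo:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("2x2 cells must be non-negative")

    @property
    def sensitivity(self) -> Optional[float]:
        return _rate(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return _rate(self.tn, self.tn + self.fp)


@dataclass(frozen=True)
class ClassMetrics:
    precision: Optional[float]
    recall: Optional[float]
    f1_score: Optional[float]
    n: int
    sensitivity: Optional[float]
    specificity: Optional[float]


@dataclass(frozen=True)
class EvalReport:
    per_class: dict[SmokingStatus, ClassMetrics]
    micro_f1: float
    confusion: ConfusionMatrix
    merged_ever: Optional[tuple[Optional[float], Optional[float]]] = None

    def to_dict(self) -> dict:
        return {
            "micro_f1": self.micro_f1,
            "per_class": {
                c.value: {
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1_score,
                    "n": m.n,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                }
                for c, m in self.per_class.items()
            },
            "merged_ever": (
                {"sensitivity": self.merged_ever[0], "specificity": self.merged_ever[1]}
                if self.merged_ever is not None
                else None
            ),
            "confusion": self.confusion.to_dict(),
        }


def _rate(num: int | float, den: int | float) -> Optional[float]:
    return None if den == 0 else num / den


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    for name, v in (("precision", precision), ("recall", recall)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if precision == 0.0 and recall == 0.0:
        return 0.0
    return 2.0 * (recall * precision) / (recall + precision)


def micro_f1(cm: ConfusionMatrix) -> float:
    """Pooled-count F1 over all classes.

    Pooled TP is the diagonal; pooled FP and FN both equal the off-diagonal
    total, so this is exactly overall accuracy for single-label data.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = float(np.trace(cm.counts))
    fp = float(total) - tp  # every miss is one FN for gold and one FP for predicted
    fn = fp
    return 2.0 * tp / (2.0 * tp + fp + fn)


def per_class_report(cm: ConfusionMatrix) -> EvalReport:
    """One-vs-rest metrics per class, plus micro-F1 and the ever-smoker merge."""
    per_class: dict[SmokingStatus, ClassMetrics] = {}
    counts = cm.counts
    total = cm.total
    for i, c in enumerate(cm.classes):
        tp = int(counts[i, i])
        gold_n = int(counts[i].sum())
        pred_n = int(counts[:, i].sum())
        tn = total - gold_n - pred_n + tp
        fp = pred_n - tp
        precision = _rate(tp, pred_n)
        recall = _rate(tp, gold_n)
        f1_val = (
            f1(precision, recall)
            if precision is not None and recall is not None
            else None
        )
        per_class[c] = ClassMetrics(
            precision=precision,
            recall=recall,
            f1_score=f1_val,
            n=gold_n,
            sensitivity=recall,  # identical by definition
            specificity=_rate(tn, tn + fp),
        )
    merged: Optional[tuple[Optional[float], Optional[float]]] = None
    if set(SMOKER_STATUSES) <= set(cm.classes):
        _, sens, spec = merge_ever(cm)
        merged = (sens, spec)
    return EvalReport(
        per_class=per_class, micro_f1=micro_f1(cm), confusion=cm, merged_ever=merged
    )


def merge_ever(cm: ConfusionMatrix) -> tuple[TwoByTwo, Optional[float], Optional[float]]:
    """Pool former/current/smoker into one *ever smoker* category.

    Confusions among the three smoker classes become correct, so merged
    sensitivity is never below any single smoker-class recall.
    """
    smoker_idx = [i for i, c in enumerate(cm.classes) if c in SMOKER_STATUSES]
    other_idx = [i for i, c in enumerate(cm.classes) if c not in SMOKER_STATUSES]
    counts = cm.counts
    tp = int(counts[np.ix_(smoker_idx, smoker_idx)].sum())
    fn = int(counts[np.ix_(smoker_idx, other_idx)].sum())
    fp = int(counts[np.ix_(other_idx, smoker_idx)].sum())
    tn = int(counts[np.ix_(other_idx, other_idx)].sum())
    box = TwoByTwo(tp=tp, fn=fn, fp=fp, tn=tn)
    return box, box.sensitivity, box.specificity


def two_by_two_eval(
    gold_flags: Iterable[bool], found_flags: Iterable[bool]
) -> tuple[TwoByTwo, Optional[float], Optional[float]]:
    """Standard 2x2 presence/absence evaluation of an extraction step."""
    gold = list(gold_flags)
    found = list(found_flags)
    if len(gold) != len(found):
        raise ValueError(f"flag lists differ in length: {len(gold)} vs {len(found)}")
    tp = sum(1 for g, f in zip(gold, found) if g and f)
    fn = sum(1 for g, f in zip(gold, found) if g and not f)
    fp = sum(1 for g, f in zip(gold, found) if not g and f)
    tn = sum(1 for g, f in zip(gold, found) if not g and not f)
    box = TwoByTwo(tp=tp, fn=fn, fp=fp, tn=tn)
    return box, box.sensitivity, box.specificity
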