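"""Information-extraction metrics for cohort evaluation.

Recall is measured against an institutional reference list of known
cases; precision against a manually reviewed sample of the predicted
patients (true negatives are not enumerable in this design, so
specificity/inverse recall is never computed).  F1 is the harmonic mean
of the two, with the usual interpretation bands.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int | None = None  # unavailable when true negatives cannot be reviewed

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0 or (self.tn is not None and self.tn < 0):
            raise ValueError("confusion counts must be non-negative")


class MetricUndefined(ValueError):
    """Raised when a metric's denominator is zero."""


class F1Band(str, enum.Enum):
    POOR = "POOR"
    ACCEPTABLE = "ACCEPTABLE"
    EXCELLENT = "EXCELLENT"
    OUTSTANDING = "OUTSTANDING"


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN)."""
    if c.tp + c.fn == 0:
        raise MetricUndefined("recall undefined: no positives in reference")
    return c.tp / (c.tp + c.fn)


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP)."""
    if c.tp + c.fp == 0:
        raise MetricUndefined("precision undefined: nothing predicted")
    return c.tp / (c.tp + c.fp)


def f1_score(r: float, p: float) -> float:
    """Harmonic mean 2rp/(r+p)."""
    if r + p == 0:
        raise MetricUndefined("F1 undefined: recall and precision both zero")
    return 2 * r * p / (r + p)


def interpret_f1(f1: float) -> F1Band:
    """Interpretation bands: [0,0.6) poor, [0.6,0.8) acceptable,
    [0.8,0.9) excellent, [0.9,1] outstanding."""
    if not (0.0 <= f1 <= 1.0):
        raise ValueError(f"F1 out of range: {f1}")
    if f1 < 0.6:
        return F1Band.POOR
    if f1 < 0.8:
        return F1Band.ACCEPTABLE
    if f1 < 0.9:
        return F1Band.EXCELLENT
    return F1Band.OUTSTANDING


def as_percent(x: float) -> int:
    """Integer percent, rounding half away from zero (0.565 -> 57)."""
    return int(Decimal(repr(x * 100)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def round2(x: float) -> float:
    """Two-decimal reporting of F1, rounding half away from zero."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CohortEvaluation:
    counts: ConfusionCounts
    recall: float
    precision: float
    f1: float
    band: F1Band

    def to_dict(self) -> dict:
        return {
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "band": self.band.value,
            "recall_pct": as_percent(self.recall),
            "precision_pct": as_percent(self.precision),
            "f1_2dp": round2(self.f1),
        }


def evaluate_cohort(predicted: Iterable[str], reference: Iterable[str],
                    reviewed: Mapping[str, bool] | None = None) -> CohortEvaluation:
    """Confusion counts and metrics for a retrieved cohort.

    ``predicted`` and ``reference`` are treated as sets.  Recall is
    computed against the reference list.  When a ``reviewed`` sample
    (patient id -> is a true case) is supplied, precision is computed on
    that sample only — the study design when exhaustive review of all
    predictions is impossible; every reviewed id must have been
    predicted.  Without a reviewed sample, precision falls back to the
    reference set.  True negatives are reported as unavailable.
    """
    pred = set(predicted)
    ref = set(reference)
    if not ref:
        raise MetricUndefined("empty reference list")

    tp = len(ref & pred)
    fn = len(ref - pred)
    if reviewed is not None:
        extra = set(reviewed) - pred
        if extra:
            raise ValueError(f"reviewed ids not in predicted set: {sorted(extra)[:5]}")
        tp_s = sum(1 for v in reviewed.values() if v)
        fp = sum(1 for v in reviewed.values() if not v)
        p = precision(ConfusionCounts(tp_s, fp, 0))
    else:
        fp = len(pred - ref)
        p = precision(ConfusionCounts(tp, fp, fn))

    r = recall(ConfusionCounts(tp, fp, fn))
    f1 = f1_score(r, p)
    return CohortEvaluation(ConfusionCounts(tp, fp, fn, tn=None), r, p, f1,
                            interpret_f1(f1))
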