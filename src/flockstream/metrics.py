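"""One-vs-rest classification metrics with macro ("overall") averaging.

Per class: accuracy, specificity, recall, precision and F-score as
percentages. The overall row is the unweighted mean of the three per-class
values; comparisons between methods are taken on unrounded overall rows.
Rounding to two decimals (half-up) happens only at presentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .signals import BEHAVIOURS

METRIC_NAMES = ("accuracy", "specificity", "recall", "precision", "f_score")


def round2(x: float) -> float:
    """Half-up rounding to two decimals (presentation only)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionCounts:
    """One-vs-rest TP/FP/TN/FN per class over window-level predictions."""

    counts: dict[str, dict[str, int]]
    total: int

    def __post_init__(self) -> None:
        for cls, c in self.counts.items():
            if any(v < 0 for v in c.values()):
                raise ValueError(f"negative count for class {cls}")
            if sum(c.values()) != self.total:
                raise ValueError(
                    f"counts for class {cls} sum to {sum(c.values())}, expected {self.total}"
                )


def confusion(
    truth: Sequence[str], pred: Sequence[str], classes: Sequence[str] = BEHAVIOURS
) -> ConfusionCounts:
    if len(truth) != len(pred):
        raise ValueError(f"length mismatch: {len(truth)} truths vs {len(pred)} predictions")
    if not truth:
        raise ValueError("empty label vectors")
    counts: dict[str, dict[str, int]] = {}
    for cls in classes:
        tp = sum(1 for t, p in zip(truth, pred) if t == cls and p == cls)
        fp = sum(1 for t, p in zip(truth, pred) if t != cls and p == cls)
        fn = sum(1 for t, p in zip(truth, pred) if t == cls and p != cls)
        tn = len(truth) - tp - fp - fn
        counts[cls] = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
    return ConfusionCounts(counts=counts, total=len(truth))


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {what}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def per_class_metrics(counts: ConfusionCounts, cls: str) -> dict[str, float]:
    """The five metrics for one class, in percent (unrounded)."""
    c = counts.counts[cls]
    tp, fp, tn, fn = c["tp"], c["fp"], c["tn"], c["fn"]
    n = tp + fp + tn + fn
    accuracy = _safe_div(tp + tn, n, f"{cls} accuracy")
    specificity = _safe_div(tn, tn + fp, f"{cls} specificity")
    recall = _safe_div(tp, tp + fn, f"{cls} recall")
    precision = _safe_div(tp, tp + fp, f"{cls} precision")
    f_score = (
        0.0
        if precision + recall == 0
        else 2 * precision * recall / (precision + recall)
    )
    return {
        "accuracy": 100 * accuracy,
        "specificity": 100 * specificity,
        "recall": 100 * recall,
        "precision": 100 * precision,
        "f_score": 100 * f_score,
    }


@dataclass
class MetricsTable:
    """Per-class metric rows (percent, unrounded)."""

    per_class: dict[str, dict[str, float]]

    @classmethod
    def from_predictions(
        cls, truth: Sequence[str], pred: Sequence[str], classes: Sequence[str] = BEHAVIOURS
    ) -> "MetricsTable":
        counts = confusion(truth, pred, classes=classes)
        return cls({c: per_class_metrics(counts, c) for c in classes})

    @classmethod
    def from_cells(cls, cells: Mapping[str, Sequence[float]]) -> "MetricsTable":
        """Build from literal per-class rows ordered as METRIC_NAMES."""
        return cls(
            {c: dict(zip(METRIC_NAMES, map(float, row))) for c, row in cells.items()}
        )

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        rows = {c: dict(m) for c, m in self.per_class.items()}
        rows["Overall"] = macro_average(self)
        df = pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)]
        return df.map(round2) if rounded else df


def macro_average(table: MetricsTable) -> dict[str, float]:
    """Unweighted mean of the per-class values, per metric (unrounded)."""
    classes = list(table.per_class)
    return {
        m: sum(table.per_class[c][m] for c in classes) / len(classes)
        for m in METRIC_NAMES
    }


def compare_methods(a: MetricsTable, b: MetricsTable) -> tuple[dict[str, float], float]:
    """Per-metric overall(a) − overall(b) on unrounded values, plus grand mean."""
    oa, ob = macro_average(a), macro_average(b)
    deltas = {m: oa[m] - ob[m] for m in METRIC_NAMES}
    grand = sum(deltas.values()) / len(deltas)
    return deltas, grand


def write_report_csv(table: MetricsTable, path: str | Path) -> None:
    df = table.to_frame(rounded=True)
    df.index.name = "class"
    df.to_csv(path)
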