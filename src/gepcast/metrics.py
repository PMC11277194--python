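"""Evaluation metrics for ordinal outbreak-level forecasts.

Besides the usual regression errors (MSE, MAPE) this module implements
the *half-credit ordinal accuracy*

    AC = (M + 0.5 D) / N * 100%

where ``M`` counts predictions exactly matching the observed level and
``D`` counts predictions exactly one level off.  The half credit for
near misses reflects the uncertainty of historical field surveys: a
one-level disagreement may be survey error rather than model error.
Misses of two levels earn nothing.

Binary classification metrics (precision, recall, F1, Matthews
correlation) are computed from confusion counts.  For the three-level
problem the primary reduction is *outbreak versus none*: level >= 2 is
positive.  One-vs-rest macro averages are also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "LevelAccuracyInput",
    "ConfusionCounts",
    "mse",
    "mape",
    "count_match_levels",
    "level_accuracy",
    "precision",
    "recall",
    "f1",
    "mcc",
    "confusion_from_levels",
    "macro_scores",
    "evaluation_report",
]

_VALID_LEVELS = frozenset({1, 2, 3})


@dataclass(frozen=True)
class LevelAccuracyInput:
    """Counts feeding the ordinal accuracy: exact matches ``M``,
    off-by-one predictions ``D``, total ``N``."""

    exact_matches: int
    off_by_one: int
    total: int

    def __post_init__(self) -> None:
        if self.total < 1:
            raise ValueError("total must be >= 1")
        if self.exact_matches < 0 or self.off_by_one < 0:
            raise ValueError("counts must be non-negative")
        if self.exact_matches + self.off_by_one > self.total:
            raise ValueError("M + D cannot exceed N")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn < 1:
            raise ValueError("at least one observation required")


def mse(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    """Mean squared error ``(1/n) sum (y - yhat)^2``."""
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if y.shape != p.shape or y.size == 0:
        raise ValueError("inputs must be equal-length and nonempty")
    return float(np.mean((y - p) ** 2))


def mape(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    """Mean absolute percentage error, in percent."""
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if y.shape != p.shape or y.size == 0:
        raise ValueError("inputs must be equal-length and nonempty")
    if np.any(y == 0):
        raise ValueError("MAPE undefined for zero true values")
    return float(np.mean(np.abs((y - p) / y)) * 100.0)


def count_match_levels(
    true_levels: Sequence[int], predicted_levels: Sequence[int]
) -> LevelAccuracyInput:
    """Count exact and off-by-one level agreements."""
    t = np.asarray(true_levels)
    p = np.asarray(predicted_levels)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("inputs must be equal-length and nonempty")
    for arr, name in ((t, "true"), (p, "predicted")):
        bad = set(np.unique(arr)) - _VALID_LEVELS
        if bad:
            raise ValueError(f"{name} levels outside {{1,2,3}}: {sorted(bad)}")
    delta = np.abs(t.astype(int) - p.astype(int))
    return LevelAccuracyInput(
        exact_matches=int(np.sum(delta == 0)),
        off_by_one=int(np.sum(delta == 1)),
        total=int(t.size),
    )


def level_accuracy(counts: LevelAccuracyInput) -> float:
    """Half-credit ordinal accuracy, in percent."""
    return 100.0 * (counts.exact_matches + 0.5 * counts.off_by_one) / counts.total


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); 0 when no positive predictions were made."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else 0.0


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN); 0 when no positives exist."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    p, r = precision(c), recall(c)
    return 2 * p * r / (p + r) if (p + r) else 0.0


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 when any
    marginal is empty."""
    denom = math.sqrt(
        float(c.tp + c.fp)
        * float(c.tp + c.fn)
        * float(c.tn + c.fp)
        * float(c.tn + c.fn)
    )
    if denom == 0.0:
        return 0.0
    return (float(c.tp) * c.tn - float(c.fp) * c.fn) / denom


def confusion_from_levels(
    true_levels: Sequence[int],
    predicted_levels: Sequence[int],
    positive_threshold: int = 2,
) -> ConfusionCounts:
    """Binarize levels (``level >= positive_threshold`` is positive,
    i.e. any recorded outbreak) and tabulate the confusion counts."""
    t = np.asarray(true_levels) >= positive_threshold
    p = np.asarray(predicted_levels) >= positive_threshold
    if t.shape != p.shape or t.size == 0:
        raise ValueError("inputs must be equal-length and nonempty")
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
    )


def macro_scores(
    true_levels: Sequence[int], predicted_levels: Sequence[int]
) -> dict[str, float]:
    """One-vs-rest macro-averaged precision, recall and F1 over the
    three levels."""
    t = np.asarray(true_levels)
    p = np.asarray(predicted_levels)
    per_class = []
    for lvl in sorted(_VALID_LEVELS):
        c = ConfusionCounts(
            tp=int(np.sum((t == lvl) & (p == lvl))),
            fp=int(np.sum((t != lvl) & (p == lvl))),
            fn=int(np.sum((t == lvl) & (p != lvl))),
            tn=int(np.sum((t != lvl) & (p != lvl))),
        )
        per_class.append((precision(c), recall(c), f1(c)))
    return {
        "macro_precision": float(np.mean([x[0] for x in per_class])),
        "macro_recall": float(np.mean([x[1] for x in per_class])),
        "macro_f1": float(np.mean([x[2] for x in per_class])),
    }


def evaluation_report(
    true_levels: Sequence[int],
    predicted_numeric: Sequence[float],
    predicted_levels: Sequence[int],
) -> dict[str, float]:
    """Full metric bundle: regression errors on the numeric
    predictions plus ordinal and binary classification scores on the
    discretized levels."""
    counts = count_match_levels(true_levels, predicted_levels)
    conf = confusion_from_levels(true_levels, predicted_levels)
    report = {
        "mse": mse(true_levels, predicted_numeric),
        "mape": mape(true_levels, predicted_numeric),
        "n": counts.total,
        "exact_matches": counts.exact_matches,
        "off_by_one": counts.off_by_one,
        "accuracy": level_accuracy(counts),
        "precision": precision(conf),
        "recall": recall(conf),
        "f1": f1(conf),
        "mcc": mcc(conf),
    }
    report.update(macro_scores(true_levels, predicted_levels))
    return report
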