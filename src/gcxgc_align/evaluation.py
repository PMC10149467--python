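"""Alignment-quality metrics.

Distribution fit between two chromatograms is scored per retention
dimension with the two-sample Kolmogorov-Smirnov statistic (lower is
better; 0 means identical empirical distributions). Anchor detection
against a known correspondence is scored with the confusion-matrix
metrics precision, recall and F1 = TP / (TP + (FN + FP)/2).

The K-S statistic is used purely as a fit metric, so no p-value is
attached.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import ks_2samp

from .anchors import AnchorSet
from .peaks import PeakTable, ValidationError

__all__ = [
    "ConfusionCounts",
    "KSResult",
    "ks_statistic",
    "ks_per_dimension",
    "confusion_counts",
    "precision_recall_f1",
    "f1_score",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValidationError("confusion counts must be >= 0")


@dataclass(frozen=True)
class KSResult:
    """K-S statistic per retention dimension, each in [0, 1]."""

    d1: float
    d2: float


def ks_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sample K-S statistic sup_t |ECDF_x(t) - ECDF_y(t)|."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValidationError("K-S statistic requires two non-empty samples")
    # the statistic is exact regardless of the p-value method; "asymp"
    # avoids the exact-p fallback warning on large tied samples
    return float(ks_2samp(x, y, method="asymp").statistic)


def ks_per_dimension(ref: PeakTable, other: PeakTable) -> KSResult:
    """K-S statistic of each retention-time dimension, reference vs other."""
    if len(ref) == 0 or len(other) == 0:
        raise ValidationError("K-S comparison requires two non-empty tables")
    return KSResult(
        d1=ks_statistic(ref.rt1(), other.rt1()),
        d2=ks_statistic(ref.rt2(), other.rt2()),
    )


def confusion_counts(predicted: AnchorSet, truth: Mapping[int, int | None]) -> ConfusionCounts:
    """Score predicted anchors against a known correspondence.

    ``truth`` maps each reference index to its aligned index, or to
    None when the compound is genuinely absent from the aligned table.

    TP: predicted pair agreeing with the truth. FP: predicted pair
    contradicting it (wrong partner, or a partner for an absent
    compound). FN: a true pair for which no pair was predicted. TN: an
    absent compound that was correctly left unmatched.
    """
    predicted_map = predicted.as_mapping()
    tp = fp = fn = tn = 0
    for r, true_a in truth.items():
        pred_a = predicted_map.get(r)
        if true_a is None:
            if pred_a is None:
                tn += 1
            else:
                fp += 1
        else:
            if pred_a is None:
                fn += 1
            elif pred_a == true_a:
                tp += 1
            else:
                fp += 1
    # predictions for reference peaks outside the truth map contradict it
    fp += sum(1 for r in predicted_map if r not in truth)
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def precision_recall_f1(c: ConfusionCounts) -> tuple[float | None, float | None, float | None]:
    """(precision, recall, F1); an undefined ratio is None, never 0.

    F1 = TP / (TP + (FN + FP)/2), equal to the harmonic mean
    2PR/(P+R) whenever both P and R are defined.
    """
    precision = c.TP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else None
    recall = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None
    denom = c.TP + (c.FN + c.FP) / 2.0
    f1 = c.TP / denom if denom > 0 else None
    return precision, recall, f1


def f1_score(precision: float, recall: float) -> float:
    """F1 from a (precision, recall) pair: the harmonic mean 2PR/(P+R)."""
    if precision < 0 or recall < 0:
        raise ValidationError("precision and recall must be >= 0")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)
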