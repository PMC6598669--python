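"""Binary-classifier evaluation against a gold-standard driver list.

The method predicts a gene set (candidates with GS below the threshold); the
gold standard is a curated driver list restricted to the evaluation universe
(by default the pathway's genes present in the network). Because driver and
non-driver classes are very unbalanced, the Matthews correlation coefficient
complements sensitivity/specificity/accuracy. ROC curves sweep the GS
threshold (lower GS = more driver-like) and are used to compare reach
orders m = 1, 2, 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import AbstractSet, Mapping

import numpy as np
import sklearn.metrics

__all__ = ["ConfusionMetrics", "RocCurve", "confusion", "roc_curve", "mcc", "compare_reach_orders"]


@dataclass(frozen=True)
class ConfusionMetrics:
    TP: int
    FP: int
    FN: int
    TN: int
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float


@dataclass(frozen=True)
class RocCurve:
    """Threshold sweep: ``fpr``/``tpr`` arrays (monotone, anchored at (0,0) and (1,1))
    and the trapezoidal ``auc``."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation coefficient; 0 by convention when any marginal is zero."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def confusion(
    predicted: AbstractSet[str],
    gold: AbstractSet[str],
    universe: AbstractSet[str],
) -> ConfusionMetrics:
    """Confusion counts and derived rates over an evaluation universe.

    Positives are ``gold & universe``; predictions outside the universe are
    an error. Rates with a zero denominator are reported as 0 (sensitivity)
    or 1 (specificity with no negatives is vacuous but kept at 1).
    """
    if not universe:
        raise ValueError("empty evaluation universe")
    extra = set(predicted) - set(universe)
    if extra:
        raise ValueError(f"predicted genes outside the universe: {sorted(extra)[:5]}")
    pos = set(gold) & set(universe)
    neg = set(universe) - pos
    tp = len(predicted & pos)
    fp = len(predicted & neg)
    fn = len(pos - predicted)
    tn = len(neg - predicted)
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 1.0
    acc = (tp + tn) / (tp + fp + fn + tn)
    return ConfusionMetrics(TP=tp, FP=fp, FN=fn, TN=tn,
                            sensitivity=sens, specificity=spec, accuracy=acc,
                            mcc=mcc(tp, fp, fn, tn))


def roc_curve(
    scores: Mapping[str, float],
    gold: AbstractSet[str],
    universe: AbstractSet[str],
) -> RocCurve:
    """ROC over GS thresholds: a gene is predicted driver when its GS is low enough.

    Every universe gene must be scored. Degenerate gold sets (empty, or
    covering the whole universe) leave the curve undefined and raise.
    """
    genes = sorted(universe)
    if not genes:
        raise ValueError("empty evaluation universe")
    missing = [g for g in genes if g not in scores]
    if missing:
        raise ValueError(f"unscored universe genes: {missing[:5]}")
    y_true = np.array([1 if g in gold else 0 for g in genes])
    if y_true.all() or not y_true.any():
        raise ValueError("degenerate gold set: empty or equal to the universe")
    # lower GS = more driver-like, so score by -GS
    y_score = np.array([-scores[g] for g in genes], dtype=float)
    fpr, tpr, _ = sklearn.metrics.roc_curve(y_true, y_score)
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(sklearn.metrics.auc(fpr, tpr)))


def compare_reach_orders(*args, **kwargs):
    """Per-m ROC/metrics comparison; delegates to :func:`pathreach.pipeline.compare_reach_orders`."""
    from .pipeline import compare_reach_orders as _impl

    return _impl(*args, **kwargs)
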