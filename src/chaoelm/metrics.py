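"""Binary diagnostic metrics: confusion counts, sensitivity/specificity,
Gmean, the sensitivity/specificity F-score, ROC curves and AUC.

The positive class is +1 (diseased).  Two conventions here deviate from
common ML usage on purpose, matching how diagnostic studies in this line of
work report results:

* ``gmean`` is the geometric mean sqrt(Sn * Sp) of sensitivity and
  specificity — a balanced-performance summary robust to class imbalance.
* ``sp_sn_fscore`` is the *harmonic* mean 2*Sp*Sn/(Sp+Sn) of sensitivity
  and specificity.  It is deliberately named to distinguish it from the
  precision/recall F1 score, which this package does not provide.

Reported table values are rounded to 4 decimals with round-half-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "RocCurve",
    "confusion",
    "accuracy",
    "sensitivity",
    "specificity",
    "gmean",
    "sp_sn_fscore",
    "roc_curve",
    "auc",
    "evaluate_scores",
    "round4",
]


def round4(x: float) -> float:
    """Round to 4 decimals, half away from zero (0.96875 -> 0.9688)."""
    if not np.isfinite(x):
        return float(x)
    return float(Decimal(repr(float(x))).quantize(Decimal("0.0001"), ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN cell counts of a binary confusion matrix."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Count TP/TN/FP/FN for +/-1 predictions against +/-1 truth."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth lengths differ")
    if not (np.all(np.isin(pred, (-1, 1))) and np.all(np.isin(truth, (-1, 1)))):
        raise ValueError("labels must be -1 or +1")
    pos = truth == 1
    return ConfusionCounts(
        tp=int(np.sum(pred[pos] == 1)),
        fn=int(np.sum(pred[pos] == -1)),
        tn=int(np.sum(pred[~pos] == -1)),
        fp=int(np.sum(pred[~pos] == 1)),
    )


def accuracy(c: ConfusionCounts) -> float:
    """Fraction of correctly classified samples, (TP + TN) / n."""
    if c.n == 0:
        raise ValueError("empty confusion matrix")
    return (c.tp + c.tn) / c.n


def sensitivity(c: ConfusionCounts) -> float:
    """True-positive rate TP / (TP + FN); NaN (with a warning) when no
    positive samples were evaluated."""
    if c.positives == 0:
        warnings.warn("no positive samples: sensitivity undefined", UserWarning, stacklevel=2)
        return float("nan")
    return c.tp / c.positives


def specificity(c: ConfusionCounts) -> float:
    """True-negative rate TN / (TN + FP); NaN (with a warning) when no
    negative samples were evaluated."""
    if c.negatives == 0:
        warnings.warn("no negative samples: specificity undefined", UserWarning, stacklevel=2)
        return float("nan")
    return c.tn / c.negatives


def gmean(sn: float, sp: float) -> float:
    """Geometric mean sqrt(Sn * Sp) of sensitivity and specificity."""
    return float(np.sqrt(sn * sp))


def sp_sn_fscore(sn: float, sp: float) -> float:
    """Harmonic mean 2*Sp*Sn / (Sp + Sn) of sensitivity and specificity
    (not the precision/recall F1).  Both zero -> 0 by convention."""
    if sn == 0 and sp == 0:
        return 0.0
    return 2.0 * sp * sn / (sp + sn)


@dataclass
class RocCurve:
    """Receiver-operating-characteristic polyline from (0,0) to (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_curve(scores: np.ndarray, truth: np.ndarray) -> RocCurve:
    """ROC points obtained by sweeping the decision threshold over every
    unique score (with +/-inf sentinels).  Both classes must be present."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth lengths differ")
    n_pos = int(np.sum(truth == 1))
    n_neg = int(np.sum(truth == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = truth[order]
    # group tied scores so each unique score yields one operating point
    distinct = np.r_[True, np.diff(s) != 0]
    tp_cum = np.cumsum(y == 1)
    fp_cum = np.cumsum(y == -1)
    idx = np.flatnonzero(np.r_[distinct[1:], True])
    tpr = np.r_[0.0, tp_cum[idx] / n_pos]
    fpr = np.r_[0.0, fp_cum[idx] / n_neg]
    thresholds = np.r_[np.inf, s[idx]]
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds)


def auc(curve: RocCurve) -> float:
    """Area under the ROC curve by the trapezoidal rule; equals the
    probability that a random positive outscores a random negative, with
    ties counted half."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


@dataclass
class MetricsReport:
    """The full metric battery for one evaluated model on one dataset."""

    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    gmean: float
    fscore: float
    auc: float | None = None

    def rounded(self) -> dict:
        out = {
            "accuracy": round4(self.accuracy),
            "sensitivity": round4(self.sensitivity),
            "specificity": round4(self.specificity),
            "gmean": round4(self.gmean),
            "fscore": round4(self.fscore),
            "tp": self.counts.tp,
            "fn": self.counts.fn,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
        }
        if self.auc is not None:
            out["auc"] = round4(self.auc)
        return out


def evaluate_scores(
    scores: np.ndarray, truth: np.ndarray, threshold: float = 0.0
) -> MetricsReport:
    """Compute the whole battery from real-valued scores and +/-1 truth.

    AUC is reported when both classes are present, omitted otherwise.
    """
    pred = np.where(np.asarray(scores) >= threshold, 1, -1)
    c = confusion(pred, truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        sn = sensitivity(c)
        sp = specificity(c)
    area = None
    if c.positives > 0 and c.negatives > 0:
        area = auc(roc_curve(scores, truth))
    return MetricsReport(
        counts=c,
        accuracy=accuracy(c),
        sensitivity=sn,
        specificity=sp,
        gmean=gmean(sn, sp),
        fscore=sp_sn_fscore(sn, sp) if not (np.isnan(sn) or np.isnan(sp)) else float("nan"),
        auc=area,
    )
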