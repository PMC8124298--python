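"""Validation metrics: confusion-matrix statistics, micro AUROC, top-k.

All (compound, target) cells are pooled into one long vector of scores and
one of labels; a cell is predicted positive iff its probability is strictly
above the cutoff.  From the pooled confusion counts come sensitivity,
specificity, precision, accuracy and Matthews correlation:

    SE  = TP / (TP + FN)
    SP  = TN / (TN + FP)
    PR  = TP / (TP + FP)
    ACC = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

AUROC is micro-averaged: the merged score/label vectors go through the
standard ROC computation, which equals the Mann-Whitney probability that a
random positive outscores a random negative (ties count one half).  Any
metric with a zero denominator is reported as None, never raised or zeroed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_auc_score

from .model import top_k_targets


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """SE/SP/PR/ACC/MCC + AUROC + top-k hit rates for one prediction run."""

    SE: float | None
    SP: float | None
    PR: float | None
    ACC: float | None
    MCC: float | None
    auroc: float | None = None
    top_k_hit_rate: dict | None = None
    cutoff: float = 0.5

    def to_dict(self) -> dict:
        return asdict(self)


def _check_aligned(probabilities, labels):
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    return p, y


def confusion_at_cutoff(
    probabilities, labels, cutoff: float = 0.5
) -> ConfusionCounts:
    """Pool all cells; predicted positive iff probability > cutoff (strict)."""
    p, y = _check_aligned(probabilities, labels)
    pred = p > cutoff
    pos = y == 1
    return ConfusionCounts(
        TP=int(np.count_nonzero(pred & pos)),
        TN=int(np.count_nonzero(~pred & ~pos)),
        FP=int(np.count_nonzero(pred & ~pos)),
        FN=int(np.count_nonzero(~pred & pos)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def compute_metrics(cc: ConfusionCounts, cutoff: float = 0.5) -> MetricsReport:
    """Confusion-derived metrics; zero denominators yield None."""
    tp, tn, fp, fn = cc.TP, cc.TN, cc.FP, cc.FN
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    mcc_den = math.sqrt((tp + fp) * (tp + fn)) * math.sqrt((tn + fp) * (tn + fn))
    return MetricsReport(
        SE=_ratio(tp, tp + fn),
        SP=_ratio(tn, tn + fp),
        PR=_ratio(tp, tp + fp),
        ACC=_ratio(tp + tn, cc.total),
        MCC=(tp * tn - fp * fn) / mcc_den if mcc_den else None,
        cutoff=cutoff,
    )


def micro_auroc(probabilities, labels) -> float | None:
    """AUROC of the merged score/label vectors (micro average).

    Returns None with a warning when the merged labels are single-class.
    """
    p, y = _check_aligned(probabilities, labels)
    p, y = p.ravel(), y.ravel()
    if y.min() == y.max():
        warnings.warn("single-class labels: AUROC undefined", stacklevel=2)
        return None
    return float(roc_auc_score(y, p))


def macro_auroc(probabilities, labels) -> float | None:
    """Per-target AUROC averaged over targets with both classes present."""
    p, y = _check_aligned(np.atleast_2d(probabilities), np.atleast_2d(labels))
    scores = []
    skipped = 0
    for j in range(y.shape[1]):
        col = y[:, j]
        if col.min() == col.max():
            skipped += 1
            continue
        scores.append(roc_auc_score(col, p[:, j]))
    if skipped:
        warnings.warn(f"{skipped} single-class targets excluded", stacklevel=2)
    return float(np.mean(scores)) if scores else None


def sensitivity_curve(probabilities, labels, cutoffs) -> list:
    """SE at each cutoff; non-increasing as the cutoff rises."""
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ValueError("cutoff grid must be nonempty")
    out = []
    for c in cutoffs:
        cc = confusion_at_cutoff(probabilities, labels, cutoff=c)
        out.append((float(c), compute_metrics(cc, cutoff=c).SE))
    return out


def top_k_hit_rate(probabilities, labels, k: int) -> float | None:
    """Fraction of compounds with >=1 active target among their top k.

    Compounds with no positive labels are excluded from the denominator;
    ranking ties break toward the lower target index.
    """
    p, y = _check_aligned(np.atleast_2d(probabilities), np.atleast_2d(labels))
    if not 1 <= k <= p.shape[1]:
        raise ValueError(f"k={k} out of range 1..{p.shape[1]}")
    hits = trials = 0
    for row_p, row_y in zip(p, y):
        if row_y.sum() == 0:
            continue
        trials += 1
        if row_y[top_k_targets(row_p, k)].any():
            hits += 1
    return hits / trials if trials else None


def evaluate_predictions(
    probabilities, labels, cutoff: float = 0.5, top_k=(15, 20)
) -> MetricsReport:
    """Full report: confusion metrics at the cutoff, AUROC, top-k hit rates."""
    report = compute_metrics(
        confusion_at_cutoff(probabilities, labels, cutoff=cutoff), cutoff=cutoff
    )
    report.auroc = micro_auroc(probabilities, labels)
    y2 = np.atleast_2d(np.asarray(labels))
    report.top_k_hit_rate = {
        int(k): top_k_hit_rate(probabilities, labels, k)
        for k in top_k
        if 1 <= k <= y2.shape[1]
    }
    return report
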