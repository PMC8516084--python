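"""Evaluation metrics for imbalanced two-class problems.

Besides plain accuracy, the metrics that actually expose a degenerate
majority-state classifier are reported: the G-mean (geometric mean of
sensitivity and specificity), the F-measure of the minority class, and the
rank-based AUC.  The AUC is the Mann-Whitney statistic — the probability that
a uniformly random positive sample outscores a uniformly random negative one,
with ties counting one half — which equals the trapezoidal area under the ROC
curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .data_io import GROUP_HI, GROUP_LOW, DataError


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with a declared positive (minority/target) class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_errors(self) -> int:
        return self.fp + self.fn


@dataclass(frozen=True)
class EvaluationReport:
    """The evaluation surface for one classification run."""

    confusion: ConfusionCounts
    accuracy: float
    auc: float
    g_mean: float
    f_minority: float
    n_errors: int
    positive: str

    def to_dict(self) -> dict:
        c = self.confusion
        return {
            "tp": c.tp,
            "fp": c.fp,
            "tn": c.tn,
            "fn": c.fn,
            "n_samples": c.total,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "g_mean": self.g_mean,
            "f_minority": self.f_minority,
            "n_errors": self.n_errors,
            "positive": self.positive,
        }


def confusion(
    predicted: Sequence[str],
    truth: Sequence[str],
    positive: str = GROUP_LOW,
) -> ConfusionCounts:
    """Tally 2x2 confusion counts with ``positive`` as the positive class."""
    if len(predicted) != len(truth):
        raise DataError(f"{len(predicted)} predictions vs {len(truth)} truth labels")
    tp = fp = tn = fn = 0
    for p, t in zip(predicted, truth):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def accuracy(cc: ConfusionCounts) -> float:
    if cc.total == 0:
        raise DataError("accuracy undefined for zero samples")
    return (cc.tp + cc.tn) / cc.total


def auc(
    scores: Sequence[float],
    truth: Sequence[str],
    positive: str = GROUP_LOW,
) -> float:
    """Rank-based (Mann-Whitney) AUC of ``scores`` oriented positive-high.

    Equivalent to the trapezoidal area under the ROC curve; ties in scores
    contribute one half.  Both classes must be present.  The direction is
    fixed by the declared positive class — no automatic flipping; an AUC
    below 0.5 is reported as-is with a log note.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise DataError("scores must be finite")
    pos = np.asarray([t == positive for t in truth], dtype=bool)
    n_pos = int(pos.sum())
    n_neg = int(len(scores) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC needs both classes present")
    ranks = rankdata(scores)  # midranks handle ties as 1/2
    value = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    if value < 0.5:
        warnings.warn(f"AUC {value:.3f} < 0.5 for positive={positive!r}", stacklevel=2)
    return float(value)


def g_mean(cc: ConfusionCounts) -> float:
    """sqrt(sensitivity x specificity); zero whenever a whole class is missed."""
    if cc.tp + cc.fn == 0 or cc.tn + cc.fp == 0:
        raise DataError("G-mean undefined: a class has no samples")
    sens = cc.tp / (cc.tp + cc.fn)
    spec = cc.tn / (cc.tn + cc.fp)
    return math.sqrt(sens * spec)


def f_measure_minority(cc: ConfusionCounts) -> float:
    """F1 of the positive (minority) class; defined as 0 when tp == 0."""
    if cc.tp + cc.fp + cc.fn == 0:
        raise DataError("F-measure undefined: no positive predictions or samples")
    if cc.tp == 0:
        return 0.0
    return 2 * cc.tp / (2 * cc.tp + cc.fp + cc.fn)


def report(
    predictions: Sequence,
    truth: Mapping[str, str] | Sequence[str],
    positive: str = GROUP_LOW,
) -> EvaluationReport:
    """Assemble the full evaluation report from a prediction list.

    ``predictions`` holds :class:`~localbalance.lbm_core.LocalPrediction`-like
    records (``test_id``, ``predicted``, ``score`` with Hi-high orientation).
    ``truth`` maps sample id to true label (or is a parallel sequence).
    """
    if isinstance(truth, Mapping):
        truths = [truth[p.test_id] for p in predictions]
    else:
        truths = list(truth)
        if len(truths) != len(predictions):
            raise DataError("truth sequence length mismatch")
    predicted = [p.predicted for p in predictions]
    scores = np.asarray([p.score for p in predictions], dtype=float)
    # LocalPrediction scores are oriented Hi-high; re-orient positive-high.
    oriented = scores if positive == GROUP_HI else -scores
    cc = confusion(predicted, truths, positive)
    return EvaluationReport(
        confusion=cc,
        accuracy=accuracy(cc),
        auc=auc(oriented, truths, positive),
        g_mean=g_mean(cc),
        f_minority=f_measure_minority(cc),
        n_errors=cc.n_errors,
        positive=positive,
    )


def report_rows(rep: EvaluationReport) -> list[tuple[str, float | int]]:
    """Rows in the conventional results-table layout."""
    return [
        ("AUC", rep.auc),
        ("accuracy", rep.accuracy),
        ("G-mean", rep.g_mean),
        ("F-meas (minority)", rep.f_minority),
        ("# errors", rep.n_errors),
    ]
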