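"""Exact ROC/AUC from rank statistics.

AUC is computed as the normalized Mann-Whitney U statistic (ties counted
half), i.e. the exact probability that a random positive outscores a random
negative — no trapezoid approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError


@dataclass
class RocResult:
    auc: float
    n_pos: int
    n_neg: int
    fpr: np.ndarray
    tpr: np.ndarray


def auc_value(scores_positive, scores_negative) -> float:
    """Normalized rank-sum AUC; exact, ties counted 1/2."""
    pos = np.asarray(scores_positive, dtype=float)
    neg = np.asarray(scores_negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DataError("both score sets must be nonempty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def roc(scores_positive, scores_negative) -> RocResult:
    """Full ROC curve plus exact AUC."""
    pos = np.asarray(scores_positive, dtype=float)
    neg = np.asarray(scores_negative, dtype=float)
    value = auc_value(pos, neg)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for t in thresholds:
        tpr.append(float(np.mean(pos >= t)))
        fpr.append(float(np.mean(neg >= t)))
    return RocResult(
        auc=value,
        n_pos=pos.size,
        n_neg=neg.size,
        fpr=np.asarray(fpr),
        tpr=np.asarray(tpr),
    )
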