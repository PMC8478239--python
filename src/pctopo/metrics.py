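"""Binary-classification metrics: Matthews correlation and rank-based AUC.

MCC is computed directly from the confusion table by the Matthews formula,
with the common zero-denominator → 0 convention. AUC is the Mann-Whitney
(midrank, half-credit for ties) statistic via scikit-learn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def mcc(table: ConfusionTable) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 when degenerate."""
    tp, fp, tn, fn = table.tp, table.fp, table.tn, table.fn
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Rank-based (Mann-Whitney) AUC of scores against binary labels."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("scores and labels must have equal length")
    if len(set(y.tolist())) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y.astype(int), s))
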