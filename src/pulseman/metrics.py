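"""Shared multi-class evaluation harness (confusion matrix, P/R/F).

Both classification modules (activity and psychological profile) report
per-class precision, recall and F-measure in percent, macro averages,
and the raw confusion matrix, all derived from a single confusion-matrix
accumulation so the invariant "F is the harmonic mean of the reported P
and R" holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError


@dataclass
class ClassificationEval:
    """Per-class precision/recall/F (%) with macro averages and counts.

    Classes with no true instances have undefined recall; they are
    reported as NaN and excluded from the macro averages.
    """

    labels: tuple[str, ...]
    confusion: pd.DataFrame = field(repr=False)   # rows = truth, cols = predicted
    per_class: pd.DataFrame = field(repr=False)   # precision/recall/f_measure (%)

    @property
    def macro_precision(self) -> float:
        return float(self.per_class["precision"].mean())

    @property
    def macro_recall(self) -> float:
        return float(self.per_class["recall"].mean())

    @property
    def macro_f(self) -> float:
        return float(self.per_class["f_measure"].mean())

    @property
    def accuracy(self) -> float:
        m = self.confusion.to_numpy()
        return float(np.trace(m) / m.sum() * 100.0)


def confusion_matrix(truth, predicted, labels: tuple[str, ...]) -> pd.DataFrame:
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ContractError("truth and predictions must have equal length")
    index = {lab: i for i, lab in enumerate(labels)}
    m = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(truth, predicted):
        m[index[t], index[p]] += 1
    return pd.DataFrame(m, index=list(labels), columns=list(labels))


def evaluate_classification(truth, predicted, labels: tuple[str, ...]
                            ) -> ClassificationEval:
    """P/R/F in percent from one accumulated confusion matrix.

    Precision of class c = fraction of instances predicted c that are c;
    recall = fraction of true c recognized as c; F = harmonic mean.
    A zero denominator yields NaN (undefined), except F which is 0 when
    both P and R are defined and zero.
    """
    conf = confusion_matrix(truth, predicted, labels)
    m = conf.to_numpy(dtype=float)
    tp = np.diag(m)
    pred_tot = m.sum(axis=0)
    true_tot = m.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_tot > 0, tp / pred_tot, np.nan)
        recall = np.where(true_tot > 0, tp / true_tot, np.nan)
        f = np.where((precision + recall) > 0,
                     2 * precision * recall / (precision + recall), 0.0)
    f = np.where(np.isnan(precision) | np.isnan(recall), np.nan, f)
    per_class = pd.DataFrame({
        "precision": precision * 100.0,
        "recall": recall * 100.0,
        "f_measure": f * 100.0,
        "support": true_tot.astype(int),
    }, index=list(labels))
    return ClassificationEval(tuple(labels), conf, per_class)
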