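"""Two-class classification metrics from confusion counts.

Computed directly from the TP/FP/TN/FN table for the designated positive
class, so the reported scalars are always reproducible from the counts.
Undefined ratios (e.g. precision with no positive predictions) are reported
as ``None`` rather than coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..errors import LabelError, ParameterError


@dataclass
class ClassificationReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    positive_class: object


def classification_metrics(y_true, y_pred, positive_class) -> ClassificationReport:
    """accuracy = (TP+TN)/N; precision = TP/(TP+FP); recall = TP/(TP+FN);
    F1 = harmonic mean of precision and recall."""
    y_true = np.asarray(y_true, dtype=object).ravel()
    y_pred = np.asarray(y_pred, dtype=object).ravel()
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ParameterError("label vectors must be equal-length and non-empty")
    seen = set(y_true.tolist()) | set(y_pred.tolist()) | {positive_class}
    if len(seen) > 2:
        raise LabelError(f"more than two classes present: {sorted(map(str, seen))}")

    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    tp = int(np.sum(pos_t & pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    fn = int(np.sum(pos_t & ~pos_p))

    acc = (tp + tn) / y_true.size
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
    return ClassificationReport(tp, fp, tn, fn, acc, precision, recall, f1,
                                positive_class)
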