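"""Confusion-matrix arithmetic shared by every classification readout.

LRRK2 mutation carriers are the positive class throughout: sensitivity is
the fraction of carriers called carriers, specificity the fraction of
sporadic-PD patients called sporadic.
"""

from __future__ import annotations

import numpy as np

from .datatypes import POSITIVE_GROUP


def confusion_counts(y_true, y_pred, positive=POSITIVE_GROUP) -> tuple[int, int, int, int]:
    """(TP, FN, TN, FP) for arbitrary (hashable) labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    is_pos = y_true == positive
    pred_pos = y_pred == positive
    tp = int((is_pos & pred_pos).sum())
    fn = int((is_pos & ~pred_pos).sum())
    tn = int((~is_pos & ~pred_pos).sum())
    fp = int((~is_pos & pred_pos).sum())
    return tp, fn, tn, fp


def sensitivity_specificity(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float]:
    """sensitivity = TP/(TP+FN), specificity = TN/(TN+FP); NaN when undefined."""
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return sens, spec
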