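"""Singlet-oriented scoring of a demultiplexing result against ground truth.

The confusion counts treat "singlet" as the positive class: a truth singlet
predicted as a singlet is a TP, a truth doublet/negative predicted as
non-singlet is a TN, a non-singlet predicted singlet is an FP, and a truth
singlet predicted non-singlet is an FN. By default a TP additionally
requires the predicted sample identity to match the true one; a truth
singlet predicted as a *different* sample then counts as an FN
(conservative). Accuracy, recall, precision and F1 follow the standard
formulas; F1 is equal to ``2TP / (2TP + FP + FN)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import DOUBLET, NEGATIVE, UNASSIGNED, LabelTable
from .errors import JoinError

#: Labels that mean "not a singlet" on either side.
NON_SINGLET_LABELS = frozenset({DOUBLET, NEGATIVE, UNASSIGNED})


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    recall: float
    precision: float
    f1: float
    degenerate: bool = False  # some ratio had a zero denominator

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _is_singlet(label: str) -> bool:
    return label not in NON_SINGLET_LABELS


def confusion_counts(
    pred: LabelTable, truth: LabelTable, require_identity_match: bool = True
) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) over the barcode intersection of ``pred`` and ``truth``."""
    p = pred.to_series()
    t = truth.to_series()
    common = p.index.intersection(t.index)
    if len(common) == 0:
        raise JoinError("prediction and truth share no barcodes")
    tp = tn = fp = fn = 0
    for b in common:
        pl, tl = p[b], t[b]
        ps, ts = _is_singlet(pl), _is_singlet(tl)
        if ts and ps:
            if require_identity_match and pl != tl:
                fn += 1
            else:
                tp += 1
        elif ts and not ps:
            fn += 1
        elif not ts and ps:
            fp += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def metrics(tp: int, tn: int, fp: int, fn: int) -> MetricsReport:
    """Accuracy, recall, precision and F1 from confusion counts.

    Ratios with a zero denominator are reported as 0 and flagged.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + tn + fp + fn
    degenerate = False

    def ratio(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    accuracy = ratio(tp + tn, total)
    recall = ratio(tp, tp + fn)
    precision = ratio(tp, tp + fp)
    f1 = ratio(2 * tp, 2 * tp + fp + fn)
    if tp == 0 and fp + fn > 0:
        # precision/recall/F1 are all vacuously 0; flag so callers don't
        # mistake this for a scored-but-poor result
        degenerate = True
    return MetricsReport(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=accuracy,
        recall=recall,
        precision=precision,
        f1=f1,
        degenerate=degenerate,
    )


def evaluate(
    pred: LabelTable, truth: LabelTable, require_identity_match: bool = True
) -> MetricsReport:
    """Convenience wrapper: confusion counts then metrics."""
    return metrics(*confusion_counts(pred, truth, require_identity_match))
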