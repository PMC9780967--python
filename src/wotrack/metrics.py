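"""Binary-classification evaluation surface for ON/OFF phase detection.

The positive class is the pre-Levodopa session (OFF state).  Reported
metrics follow the standard confusion-matrix identities, in percent:

    accuracy    = (tp + tn) / (tp + tn + fp + fn) * 100
    recall      = tp / (tp + fn) * 100
    precision   = tp / (tp + fp) * 100
    F1          = 2 tp / (2 tp + fn + fp) * 100
    specificity = tn / (tn + fp) * 100

plus the ROC curve, its trapezoidal AUC, and the operating point closest
(Euclidean) to the ideal corner {FPR, TPR} = {0, 1}.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

from ._utils import round_half_up

POSITIVE = "pre"      # OFF state
NEGATIVE = "post"     # ON state


def confusion(labels, predicted):
    """(tp, tn, fp, fn) counts with positive = pre-Levodopa (OFF)."""
    labels = np.asarray(labels)
    predicted = np.asarray(predicted)
    if labels.shape != predicted.shape:
        raise ValueError("label vectors must have equal length")
    for arr in (labels, predicted):
        bad = set(np.unique(arr)) - {POSITIVE, NEGATIVE}
        if bad:
            raise ValueError(f"unknown labels {bad}")
    pos, hit = labels == POSITIVE, predicted == POSITIVE
    tp = int(np.sum(pos & hit))
    tn = int(np.sum(~pos & ~hit))
    fp = int(np.sum(~pos & hit))
    fn = int(np.sum(pos & ~hit))
    return tp, tn, fp, fn


def metrics(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Percent metrics from confusion counts; undefined ratios become NaN."""
    n = tp + tn + fp + fn
    if n <= 0:
        raise ValueError("empty confusion matrix")

    def ratio(num, den):
        return num / den * 100.0 if den > 0 else float("nan")

    return {
        "accuracy_pct": round_half_up(ratio(tp + tn, n)),
        "recall_pct": round_half_up(ratio(tp, tp + fn)),
        "precision_pct": round_half_up(ratio(tp, tp + fp)),
        "f1_pct": round_half_up(ratio(2 * tp, 2 * tp + fn + fp)),
        "specificity_pct": round_half_up(ratio(tn, tn + fp)),
    }


def roc_auc(scores, labels):
    """ROC points, trapezoidal AUC and the closest-to-(0,1) operating point.

    Scores are probability-like values for the positive (pre/OFF) class;
    tied scores are swept together (standard step construction).
    """
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(labels) == POSITIVE).astype(int)
    if y.min() == y.max():
        raise ValueError("ROC needs at least one observation of each class")
    fpr, tpr, thresholds = _roc_curve(y, scores)
    area = float(_auc(fpr, tpr))
    d2 = fpr ** 2 + (1.0 - tpr) ** 2
    i = int(np.argmin(d2))
    return {
        "roc": list(zip(fpr.tolist(), tpr.tolist())),
        "auc": area,
        "operating_point": {
            "fpr": float(fpr[i]),
            "tpr": float(tpr[i]),
            "threshold": float(thresholds[i]),
        },
    }


@dataclass
class EvalReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy_pct: float = field(init=False)
    recall_pct: float = field(init=False)
    precision_pct: float = field(init=False)
    f1_pct: float = field(init=False)
    specificity_pct: float = field(init=False)
    roc: list | None = None
    auc: float | None = None
    operating_point: dict | None = None

    def __post_init__(self):
        for k, v in metrics(self.tp, self.tn, self.fp, self.fn).items():
            setattr(self, k, v)

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(labels, predicted, scores=None) -> EvalReport:
    """Full evaluation from true labels, hard predictions and (optional) scores."""
    tp, tn, fp, fn = confusion(labels, predicted)
    rep = EvalReport(tp=tp, tn=tn, fp=fp, fn=fn)
    if scores is not None:
        r = roc_auc(scores, labels)
        rep.roc, rep.auc, rep.operating_point = r["roc"], r["auc"], r["operating_point"]
    return rep
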