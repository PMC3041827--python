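"""Confusion-matrix metrics, rank-based AUC and the antibody-array
confirmation rule."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.N == 0:
            raise ValueError("all four counts are zero")

    @property
    def N(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class EvalReport:
    SEN: float
    SP: float
    ACC: float
    MCC: float
    counts: ConfusionCounts
    AUC: float | None = None
    mcc_degenerate: bool = False
    extras: dict = field(default_factory=dict)

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Display rounding used in the performance tables; full precision
        is kept on the object itself."""
        out = {k: round(getattr(self, k), ndigits) for k in ("SEN", "SP", "ACC", "MCC")}
        if self.AUC is not None:
            out["AUC"] = round(self.AUC, ndigits)
        return out


def confusion_metrics(counts: ConfusionCounts) -> EvalReport:
    """SEN = TP/(TP+FN); SP = TN/(TN+FP); ACC = (TP+TN)/N;
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN)).

    A zero factor under the MCC root makes MCC degenerate: reported as 0
    with the `mcc_degenerate` flag set. SEN/SP are 0 when their own
    denominators are empty.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    sen = tp / (tp + fn) if (tp + fn) else 0.0
    sp = tn / (tn + fp) if (tn + fp) else 0.0
    acc = (tp + tn) / counts.N
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc, degenerate = 0.0, True
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(float(denom))
        degenerate = False
    return EvalReport(SEN=sen, SP=sp, ACC=acc, MCC=float(mcc),
                      counts=counts, mcc_degenerate=degenerate)


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores contribute 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = ~pos
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        TN=int(((y_true == -1) & (y_pred == -1)).sum()),
        FP=int(((y_true == -1) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == -1)).sum()),
    )


def array_confirmation(signal: float, background: float, fold: float = 5.0) -> bool:
    """True iff the array signal is at least `fold` times the background
    (the manufacturer's presence rule; >= semantics at the boundary)."""
    if background <= 0:
        raise ValueError("background must be positive")
    if signal < 0:
        raise ValueError("signal must be non-negative")
    return signal >= fold * background
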