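"""Per-feature F-score computation, ranking and threshold filtering.

The F-score of a feature is the squared separation of its class means
around the pooled mean, divided by the sum of the per-class sample
variances:

    F = ((m+ - m)^2 + (m- - m)^2) /
        ( (1/(n+ - 1)) * sum((x+ - m+)^2) + (1/(n- - 1)) * sum((x- - m-)^2) )

Larger F means more discriminative. A zero denominator yields 0 when the
class means coincide and +inf when they differ (a perfectly separating
feature is never discarded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def f_score(values_pos, values_neg) -> float:
    """F-score of one feature from its positive- and negative-class values."""
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("each class needs at least 2 values for an F-score")
    pooled_mean = np.concatenate([pos, neg]).mean()
    mp, mn = pos.mean(), neg.mean()
    numerator = (mp - pooled_mean) ** 2 + (mn - pooled_mean) ** 2
    denominator = pos.var(ddof=1) + neg.var(ddof=1)
    if denominator == 0.0:
        return 0.0 if numerator == 0.0 else float("inf")
    return float(numerator / denominator)


@dataclass
class LabeledFeatureMatrix:
    """Proteins x features matrix with +1/-1 class labels."""

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: list[str] | None = None
    registry_version: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise ValueError("row count must equal label count")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +1 / -1")

    @property
    def n_pos(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.labels == -1).sum())


@dataclass
class FScoreReport:
    """Per-feature F-scores with descending ranks (1 = most discriminative)."""

    scores: np.ndarray
    ranks: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def to_frame(self, threshold: float | None = None) -> pd.DataFrame:
        names = self.feature_names or [f"f{i}" for i in range(self.scores.size)]
        df = pd.DataFrame({"feature": names, "f_score": self.scores, "rank": self.ranks})
        if threshold is not None:
            df["selected"] = self.scores >= threshold
        return df


def rank_features(data: LabeledFeatureMatrix) -> FScoreReport:
    """F-score each column; rank descending, ties broken by ascending
    column index. Invariant to row permutation."""
    if data.n_pos < 2 or data.n_neg < 2:
        raise ValueError("need at least 2 proteins per class")
    pos = data.matrix[data.labels == 1]
    neg = data.matrix[data.labels == -1]
    scores = np.array([f_score(pos[:, j], neg[:, j]) for j in range(data.matrix.shape[1])])
    # stable sort on (-score, index) => deterministic tie-breaking
    order = np.lexsort((np.arange(scores.size), -scores))
    ranks = np.empty(scores.size, dtype=int)
    ranks[order] = np.arange(1, scores.size + 1)
    return FScoreReport(scores=scores, ranks=ranks,
                        feature_names=list(data.feature_names or []))


def filter_by_threshold(report: FScoreReport, threshold: float) -> np.ndarray:
    """Indices of features with F-score >= threshold, in registry order."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    selected = np.where(report.scores >= threshold)[0]
    if selected.size == 0:
        raise ValueError(
            f"threshold {threshold} removes every feature "
            f"(max F-score is {np.max(report.scores)}); lower the threshold"
        )
    return selected
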