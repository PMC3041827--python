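"""Nested threshold-search training pipeline for the RBF-kernel classifier.

For each candidate F-score threshold: keep the features at or above it,
run `repeats` random stratified half-splits, grid-search (C, gamma) on
each sub-training half and score the misclassification fraction on the
matching sub-validation half, then average. The threshold with the lowest
average validation error wins (ties go to the smaller threshold, i.e.
more features). The final classifier is refit on all rows using the
winning feature set and a (C, gamma) chosen by re-running the repeated
split protocol on the full data.

Models serialize to JSON holding the kernel expansion explicitly
(support vectors, dual coefficients, intercept), so prediction after a
round-trip is bit-identical and needs no solver state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .selection import FScoreReport, LabeledFeatureMatrix, filter_by_threshold, rank_features

DEFAULT_C_GRID = [2.0**p for p in range(-5, 16, 2)]
DEFAULT_GAMMA_GRID = [2.0**p for p in range(-15, 4, 2)]


@dataclass
class TrainingConfig:
    threshold_candidates: list[float] | None = None  # None -> F-score quantiles 0..0.9
    C_grid: list[float] = field(default_factory=lambda: list(DEFAULT_C_GRID))
    gamma_grid: list[float] = field(default_factory=lambda: list(DEFAULT_GAMMA_GRID))
    repeats: int = 5
    split_fraction: float = 0.5
    seed: int = 0
    scaling: str = "minmax"  # none | minmax | zscore
    class_weight: str | None = None  # None or "balanced"

    def __post_init__(self) -> None:
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("C and gamma grids must be non-empty")
        if any(c <= 0 for c in self.C_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ValueError("C and gamma must be positive")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.scaling not in ("none", "minmax", "zscore"):
            raise ValueError(f"unknown scaling {self.scaling!r}")


# --- scaling --------------------------------------------------------------


def fit_scaler(X: np.ndarray, mode: str) -> dict:
    if mode == "none":
        return {"mode": "none"}
    if mode == "minmax":
        lo = X.min(axis=0)
        span = X.max(axis=0) - lo
        span[span == 0] = 1.0
        return {"mode": "minmax", "offset": lo, "scale": span}
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return {"mode": "zscore", "offset": mu, "scale": sd}


def apply_scaler(X: np.ndarray, scaler: dict) -> np.ndarray:
    if scaler["mode"] == "none":
        return np.asarray(X, dtype=float)
    return (np.asarray(X, dtype=float) - scaler["offset"]) / scaler["scale"]


# --- splitting ------------------------------------------------------------


def split_half(data: LabeledFeatureMatrix, seed: int,
               fraction: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random split into (sub-train, sub-validation) row indices.

    Per class the sub-training half takes ceil(fraction * n) rows, so
    sizes differ by at most one per class. Deterministic given the seed.
    """
    labels = data.labels
    if data.n_pos < 2 or data.n_neg < 2:
        raise ValueError("need at least 2 rows per class to split")
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in (1, -1):
        rows = np.where(labels == cls)[0]
        rng.shuffle(rows)
        k = int(np.ceil(fraction * rows.size))
        train_idx.append(rows[:k])
        val_idx.append(rows[k:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


# --- grid search ----------------------------------------------------------


def _fit_svc(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
             class_weight: str | None) -> SVC:
    clf = SVC(C=C, gamma=gamma, kernel="rbf", class_weight=class_weight)
    clf.fit(X, y)
    return clf


def grid_search_fit(X_train: np.ndarray, y_train: np.ndarray,
                    X_val: np.ndarray, y_val: np.ndarray,
                    config: TrainingConfig) -> tuple[float, float, float]:
    """Exhaustive (C, gamma) search; returns (best C, best gamma,
    validation error). Ties break toward smaller C, then smaller gamma."""
    if len(np.unique(y_train)) < 2:
        raise ValueError("sub-training set contains a single class")
    best = None
    for C in sorted(config.C_grid):
        for gamma in sorted(config.gamma_grid):
            clf = _fit_svc(X_train, y_train, C, gamma, config.class_weight)
            err = float(np.mean(clf.predict(X_val) != y_val))
            if best is None or err < best[2]:
                best = (C, gamma, err)
    return best


# --- model ----------------------------------------------------------------


@dataclass
class TrainedModel:
    registry_version: str
    threshold: float
    selected_indices: list[int]
    scaler: dict
    C: float
    gamma: float
    support_vectors: np.ndarray  # (n_sv, n_selected), scaled space
    dual_coef: np.ndarray  # (n_sv,)
    intercept: float
    seed: int
    error_table: list[dict]  # per-threshold average validation errors

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """RBF kernel expansion: sum_i a_i exp(-gamma ||x - sv_i||^2) + b."""
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma * d2) @ self.dual_coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "registry_version": self.registry_version,
            "threshold": self.threshold,
            "selected_indices": list(map(int, self.selected_indices)),
            "scaler": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.scaler.items()
            },
            "C": self.C,
            "gamma": self.gamma,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "seed": self.seed,
            "error_table": self.error_table,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        scaler = dict(d["scaler"])
        for k in ("offset", "scale"):
            if k in scaler:
                scaler[k] = np.asarray(scaler[k], dtype=float)
        return cls(
            registry_version=d["registry_version"],
            threshold=d["threshold"],
            selected_indices=list(d["selected_indices"]),
            scaler=scaler,
            C=d["C"],
            gamma=d["gamma"],
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=d["intercept"],
            seed=d["seed"],
            error_table=list(d["error_table"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# --- training -------------------------------------------------------------


def default_threshold_candidates(report: FScoreReport) -> list[float]:
    """Empirical quantiles {0, 0.1, ..., 0.9} of the finite F-scores."""
    finite = report.scores[np.isfinite(report.scores)]
    if finite.size == 0:
        return [0.0]
    qs = np.quantile(finite, np.arange(0.0, 1.0, 0.1))
    # dedupe while keeping order; quantile 0 maps to threshold 0 (keep all)
    out, seen = [], set()
    for q in [0.0, *qs[1:]]:
        q = float(q)
        if q not in seen:
            seen.add(q)
            out.append(q)
    return out


def _average_validation_error(data: LabeledFeatureMatrix, cols: np.ndarray,
                              config: TrainingConfig, seed_base: int) -> tuple[float, list[dict]]:
    errors, cells = [], []
    for r in range(config.repeats):
        split_seed = seed_base + r
        tr, va = split_half(data, seed=split_seed, fraction=config.split_fraction)
        X_tr = data.matrix[np.ix_(tr, cols)]
        X_va = data.matrix[np.ix_(va, cols)]
        scaler = fit_scaler(X_tr, config.scaling)
        C, gamma, err = grid_search_fit(
            apply_scaler(X_tr, scaler), data.labels[tr],
            apply_scaler(X_va, scaler), data.labels[va], config,
        )
        errors.append(err)
        cells.append({"repeat": r, "split_seed": split_seed, "C": C,
                      "gamma": gamma, "error": err})
    return float(np.mean(errors)), cells


def select_threshold_and_train(data: LabeledFeatureMatrix,
                               config: TrainingConfig) -> TrainedModel:
    """Full nested procedure: threshold search, then final refit."""
    report = rank_features(data)
    thresholds = (config.threshold_candidates
                  if config.threshold_candidates is not None
                  else default_threshold_candidates(report))
    if not thresholds:
        raise ValueError("empty threshold candidate list")

    error_table = []
    best_thr, best_err = None, np.inf
    any_valid = False
    for ti, thr in enumerate(sorted(thresholds)):
        try:
            cols = filter_by_threshold(report, thr)
        except ValueError:
            error_table.append({"threshold": thr, "n_features": 0,
                                "avg_error": None, "cells": []})
            continue
        any_valid = True
        avg_err, cells = _average_validation_error(
            data, cols, config, seed_base=config.seed + 1000 * ti)
        error_table.append({"threshold": thr, "n_features": int(cols.size),
                            "avg_error": avg_err, "cells": cells})
        if avg_err < best_err:  # ties keep the earlier (smaller) threshold
            best_thr, best_err = thr, avg_err
    if not any_valid:
        raise ValueError("every candidate threshold removes all features")

    cols = filter_by_threshold(report, best_thr)
    # final (C, gamma): repeated-split search restricted to the winning
    # feature set, then refit on every row
    final_errors: dict[tuple[float, float], list[float]] = {}
    for r in range(config.repeats):
        tr, va = split_half(data, seed=config.seed + 900_000 + r,
                            fraction=config.split_fraction)
        X_tr = data.matrix[np.ix_(tr, cols)]
        X_va = data.matrix[np.ix_(va, cols)]
        scaler = fit_scaler(X_tr, config.scaling)
        Xt, Xv = apply_scaler(X_tr, scaler), apply_scaler(X_va, scaler)
        for C in sorted(config.C_grid):
            for gamma in sorted(config.gamma_grid):
                clf = _fit_svc(Xt, data.labels[tr], C, gamma, config.class_weight)
                err = float(np.mean(clf.predict(Xv) != data.labels[va]))
                final_errors.setdefault((C, gamma), []).append(err)
    (C, gamma), _err = min(final_errors.items(),
                           key=lambda kv: (float(np.mean(kv[1])), kv[0]))

    X_full = data.matrix[:, cols]
    scaler = fit_scaler(X_full, config.scaling)
    clf = _fit_svc(apply_scaler(X_full, scaler), data.labels, C, gamma,
                   config.class_weight)
    return TrainedModel(
        registry_version=data.registry_version,
        threshold=float(best_thr),
        selected_indices=[int(c) for c in cols],
        scaler=scaler,
        C=float(C),
        gamma=float(gamma),
        support_vectors=np.asarray(clf.support_vectors_, dtype=float),
        dual_coef=np.asarray(clf.dual_coef_[0], dtype=float),
        intercept=float(clf.intercept_[0]),
        seed=config.seed,
        error_table=error_table,
    )


def predict(model: TrainedModel, matrix: np.ndarray,
            registry_version: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Apply a trained model to a full-width feature matrix.

    Returns (labels in {-1, +1}, decision scores). Zero scores map to +1.
    """
    if registry_version is not None and registry_version != model.registry_version:
        raise ValueError(
            f"registry mismatch: model={model.registry_version!r}, "
            f"data={registry_version!r}"
        )
    X = np.asarray(matrix, dtype=float)[:, model.selected_indices]
    scores = model.decision_function(apply_scaler(X, model.scaler))
    labels = np.where(scores >= 0, 1, -1)
    return labels, scores
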