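"""Paired tumor/control fold-change screening.

For each gene, K_exp counts the tissue pairs whose expression fold-change
reaches a cutoff (2-fold by default). Significance comes from a
within-pair label-swap permutation null: under no effect, tumor and
control values of a pair are exchangeable, so each pair's ratio flips
sign independently with probability 1/2.

Direction handling: for `up` and `down` the permutation statistic is
K_exp itself. The undirected count (K_up + K_down) is invariant under
label swaps, so for direction `either` the permuted statistic is the
directional maximum max(K_up, K_down) — a gene is extreme when its
exceedances concentrate on one side. A binomial alternative
(K_up ~ Binomial(K_up + K_down, 1/2), two-sided) is available via
`method="binomial"`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest

DIRECTIONS = ("up", "down", "either")


@dataclass
class PairedExpressionMatrix:
    """Genes x pairs table of strictly positive (tumor, control) values."""

    tumor: np.ndarray  # (genes, pairs)
    control: np.ndarray
    gene_ids: list[str]
    pair_ids: list[str]

    def __post_init__(self) -> None:
        self.tumor = np.asarray(self.tumor, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        if self.tumor.shape != self.control.shape:
            raise ValueError("tumor and control must have identical shape")
        if self.tumor.shape != (len(self.gene_ids), len(self.pair_ids)):
            raise ValueError("shape does not match gene/pair ids")
        if np.any(self.tumor <= 0) or np.any(self.control <= 0):
            raise ValueError("expression values must be strictly positive")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairedExpressionMatrix":
        """Columns: gene_id, then <pair>_tumor / <pair>_control pairs."""
        df = pd.read_csv(path, sep="\t")
        gene_ids = df.iloc[:, 0].astype(str).tolist()
        tumor_cols = [c for c in df.columns[1:] if c.endswith("_tumor")]
        pair_ids = [c[: -len("_tumor")] for c in tumor_cols]
        control_cols = [f"{p}_control" for p in pair_ids]
        missing = [c for c in control_cols if c not in df.columns]
        if not pair_ids or missing:
            raise ValueError("expected alternating <pair>_tumor/<pair>_control columns")
        return cls(df[tumor_cols].to_numpy(), df[control_cols].to_numpy(),
                   gene_ids, pair_ids)

    def to_tsv(self, path: str | Path) -> None:
        data = {"gene_id": self.gene_ids}
        for j, pid in enumerate(self.pair_ids):
            data[f"{pid}_tumor"] = self.tumor[:, j]
            data[f"{pid}_control"] = self.control[:, j]
        pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def _check_fold(fold: float) -> None:
    if fold < 1:
        raise ValueError(f"fold cutoff must be >= 1, got {fold}")


def k_exp(tumor, control, fold: float = 2.0, direction: str = "either") -> int:
    """Number of pairs whose fold-change reaches `fold`.

    up: tumor/control >= fold; down: control/tumor >= fold;
    either: max of the two ratios >= fold.
    """
    _check_fold(fold)
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    tumor = np.asarray(tumor, dtype=float)
    control = np.asarray(control, dtype=float)
    if np.any(tumor <= 0) or np.any(control <= 0):
        raise ValueError("expression values must be strictly positive")
    up = tumor / control >= fold
    down = control / tumor >= fold
    if direction == "up":
        return int(up.sum())
    if direction == "down":
        return int(down.sum())
    return int((up | down).sum())


def _perm_stats(up: np.ndarray, down: np.ndarray, flips: np.ndarray,
                direction: str) -> np.ndarray:
    """Permutation statistics for one gene.

    up/down: boolean exceedance per pair; flips: (n_perm, n_pairs) 0/1,
    1 = swap the pair's labels (so its up/down exceedances exchange).
    """
    k_up = flips @ down + (1 - flips) @ up
    if direction == "up":
        return k_up
    k_total = int(up.sum() + down.sum())
    k_down = k_total - k_up
    if direction == "down":
        return k_down
    return np.maximum(k_up, k_down)


def _observed_stat(up: np.ndarray, down: np.ndarray, direction: str) -> int:
    if direction == "up":
        return int(up.sum())
    if direction == "down":
        return int(down.sum())
    return int(max(up.sum(), down.sum()))


def k_exp_pvalue(tumor, control, fold: float = 2.0, direction: str = "either",
                 n_perm: int = 10_000, seed: int = 0,
                 method: str = "permutation") -> float:
    """Permutation p-value for one gene's K_exp.

    p = (1 + #{permuted statistic >= observed}) / (1 + n_perm).
    """
    _check_fold(fold)
    tumor = np.asarray(tumor, dtype=float)
    control = np.asarray(control, dtype=float)
    if tumor.size < 2:
        raise ValueError("need at least 2 pairs")
    up = tumor / control >= fold
    down = control / tumor >= fold
    if method == "binomial":
        return _binomial_pvalue(int(up.sum()), int(down.sum()), direction)
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=(n_perm, tumor.size))
    stats = _perm_stats(up.astype(float), down.astype(float), flips, direction)
    obs = _observed_stat(up, down, direction)
    return float((1 + (stats >= obs).sum()) / (1 + n_perm))


def _binomial_pvalue(k_up: int, k_down: int, direction: str) -> float:
    n = k_up + k_down
    if n == 0:
        return 1.0
    if direction == "up":
        return float(binomtest(k_up, n, 0.5, alternative="greater").pvalue)
    if direction == "down":
        return float(binomtest(k_down, n, 0.5, alternative="greater").pvalue)
    return float(binomtest(k_up, n, 0.5, alternative="two-sided").pvalue)


@dataclass
class DEResult:
    gene_id: str
    k_exp: int
    direction: str  # up | down | mixed
    p_value: float
    de_flag: bool


def call_de(matrix: PairedExpressionMatrix, fold: float = 2.0,
            alpha: float = 0.05, direction: str = "either",
            n_perm: int = 10_000, seed: int = 0,
            method: str = "permutation") -> list[DEResult]:
    """Per-gene K_exp, dominant direction, p-value and DE flag.

    One shared set of seeded pair flips is drawn for the whole matrix, so
    a gene's result is invariant to the presence of other genes only up to
    the shared permutation draw; results are ordered by ascending p-value,
    ties by gene id. No multiple-testing correction is applied (`alpha`
    acts on raw p-values), matching the screening rule this implements.
    """
    _check_fold(fold)
    if method == "permutation" and n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    up = (matrix.tumor / matrix.control >= fold)
    down = (matrix.control / matrix.tumor >= fold)
    k_up = up.sum(axis=1)
    k_down = down.sum(axis=1)
    if direction == "up":
        k_obs = k_up
    elif direction == "down":
        k_obs = k_down
    else:
        k_obs = k_up + k_down
    stat_obs = np.maximum(k_up, k_down) if direction == "either" else k_obs

    n_genes = len(matrix.gene_ids)
    if method == "binomial":
        pvals = np.array([
            _binomial_pvalue(int(k_up[g]), int(k_down[g]), direction)
            for g in range(n_genes)
        ])
    else:
        rng = np.random.default_rng(seed)
        flips = rng.integers(0, 2, size=(n_perm, matrix.n_pairs)).astype(float)
        # (genes, n_perm): permuted K_up for every gene under shared flips
        perm_up = up @ flips.T + down @ (1 - flips).T
        if direction == "up":
            perm_stat = perm_up
        elif direction == "down":
            perm_stat = (k_up + k_down)[:, None] - perm_up
        else:
            perm_stat = np.maximum(perm_up, (k_up + k_down)[:, None] - perm_up)
        pvals = (1 + (perm_stat >= stat_obs[:, None]).sum(axis=1)) / (1 + n_perm)

    results = []
    for g, gid in enumerate(matrix.gene_ids):
        if k_up[g] > 0 and k_down[g] == 0:
            dir_g = "up"
        elif k_down[g] > 0 and k_up[g] == 0:
            dir_g = "down"
        elif k_up[g] == 0 and k_down[g] == 0:
            dir_g = "mixed"
        else:
            dir_g = "mixed" if min(k_up[g], k_down[g]) / max(k_up[g], k_down[g]) > 0.5 \
                else ("up" if k_up[g] > k_down[g] else "down")
        results.append(DEResult(gene_id=gid, k_exp=int(k_obs[g]), direction=dir_g,
                                p_value=float(pvals[g]), de_flag=bool(pvals[g] < alpha)))
    results.sort(key=lambda r: (r.p_value, r.gene_id))
    return results


def de_results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.k_exp, r.direction, r.p_value, r.de_flag) for r in results],
        columns=["gene_id", "k_exp", "direction", "p_value", "de_flag"],
    )
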