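"""Synthetic fixtures: two-class protein sequences, family tables, and
paired expression matrices with planted fold-change effects.

Every generator is a pure function of its spec (the seed included), so
fixtures are regenerated at test time instead of being stored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features.records import ProteinRecord
from .features.tables import HUMAN_BACKGROUND_FREQ, STANDARD_AA
from .negatives import FamilyTable

HELIX_RESIDUES = "ALEM"
POSITIVE_RESIDUES = "KR"
HYDROPHOBIC_CORE = "LAVIF"


@dataclass
class SimulationSpec:
    # protein generator
    n_pos: int = 200
    n_neg: int = 400
    length_range: tuple[int, int] = (120, 400)
    signal_prefix_prob_pos: float = 0.9
    signal_prefix_prob_neg: float = 0.05
    positive_charge_boost: float = 2.0   # multiplier on K/R background freq
    helix_boost: float = 1.6             # multiplier on helix-residue freq
    # family generator
    n_families: int = 50
    family_size_mean: float = 8.0
    contaminated_fraction: float = 0.3
    # expression generator
    n_genes: int = 1000
    n_pairs: int = 80
    planted_fraction: float = 0.05
    fold_effect: float = 4.0
    affected_pair_fraction: float = 1.0
    noise_sd: float = 0.5               # SD of lognormal noise (natural log)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pos", "n_neg", "n_families", "n_genes", "n_pairs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("signal_prefix_prob_pos", "signal_prefix_prob_neg",
                     "contaminated_fraction", "planted_fraction",
                     "affected_pair_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def _tilted_frequencies(charge_boost: float, helix_boost: float) -> np.ndarray:
    freqs = np.array([HUMAN_BACKGROUND_FREQ[aa] for aa in STANDARD_AA])
    for i, aa in enumerate(STANDARD_AA):
        if aa in POSITIVE_RESIDUES:
            freqs[i] *= charge_boost
        if aa in HELIX_RESIDUES:
            freqs[i] *= helix_boost
    return freqs / freqs.sum()


def _random_sequence(rng: np.random.Generator, length: int, freqs: np.ndarray) -> str:
    idx = rng.choice(len(STANDARD_AA), size=length, p=freqs)
    return "".join(STANDARD_AA[i] for i in idx)


def _signal_prefix(rng: np.random.Generator) -> str:
    """Signal-peptide-like prefix: M + basic n-region + hydrophobic h-region
    + small polar c-region."""
    n_region = "".join(rng.choice(list("KR"), size=rng.integers(2, 4)))
    h_len = int(rng.integers(9, 13))
    h_region = "".join(rng.choice(list(HYDROPHOBIC_CORE), size=h_len))
    c_region = "".join(rng.choice(list("ASG"), size=4)) + "A"
    return "M" + n_region + h_region + c_region


def simulate_proteins(spec: SimulationSpec) -> tuple[list[ProteinRecord], dict[str, int]]:
    """Two-class sequence set; returns (records, labels) with labels in
    {+1 excretory-like, -1 background}."""
    rng = np.random.default_rng(spec.seed)
    background = np.array([HUMAN_BACKGROUND_FREQ[aa] for aa in STANDARD_AA])
    background = background / background.sum()
    tilted = _tilted_frequencies(spec.positive_charge_boost, spec.helix_boost)
    records, labels = [], {}
    for cls, n, freqs, p_signal in (
        (1, spec.n_pos, tilted, spec.signal_prefix_prob_pos),
        (-1, spec.n_neg, background, spec.signal_prefix_prob_neg),
    ):
        tag = "POS" if cls == 1 else "NEG"
        for i in range(n):
            length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            body = _random_sequence(rng, length, freqs)
            if rng.random() < p_signal:
                body = _signal_prefix(rng) + body
            rid = f"{tag}{i:05d}"
            records.append(ProteinRecord(rid, body))
            labels[rid] = cls
    return records, labels


def simulate_family_table(spec: SimulationSpec) -> tuple[FamilyTable, list[str]]:
    """Family table with a stated fraction of positive-contaminated
    families; returns (table, positive id list)."""
    rng = np.random.default_rng(spec.seed + 1)
    pairs: list[tuple[str, str]] = []
    positives: list[str] = []
    pid = 0
    n_contaminated = int(round(spec.contaminated_fraction * spec.n_families))
    for fam_i in range(spec.n_families):
        fam = f"FAM{fam_i:04d}"
        size = 1 + rng.poisson(max(spec.family_size_mean - 1, 0.0))
        members = []
        for _m in range(size):
            protein = f"PROT{pid:06d}"
            pid += 1
            members.append(protein)
            pairs.append((protein, fam))
        if fam_i < n_contaminated:
            positives.append(members[int(rng.integers(0, len(members)))])
    return FamilyTable(pairs), positives


def simulate_paired_expression(spec: SimulationSpec):
    """Paired tumor/control matrix with planted fold-change genes.

    Returns (PairedExpressionMatrix, truth) where truth maps gene id ->
    True for planted genes. Baselines are per-gene lognormal; planted
    genes get the fold effect (up) in a spec-chosen fraction of pairs.
    """
    from .de import PairedExpressionMatrix

    rng = np.random.default_rng(spec.seed + 2)
    g, p = spec.n_genes, spec.n_pairs
    baseline = np.exp(rng.normal(3.0, 1.0, size=g))[:, None]
    tumor = baseline * np.exp(rng.normal(0.0, spec.noise_sd, size=(g, p)))
    control = baseline * np.exp(rng.normal(0.0, spec.noise_sd, size=(g, p)))
    n_planted = int(round(spec.planted_fraction * g))
    planted = rng.choice(g, size=n_planted, replace=False)
    n_affected = int(round(spec.affected_pair_fraction * p))
    for gi in planted:
        cols = rng.choice(p, size=n_affected, replace=False)
        tumor[gi, cols] *= spec.fold_effect
    gene_ids = [f"GENE{i:05d}" for i in range(g)]
    pair_ids = [f"pair{j:03d}" for j in range(p)]
    truth = {gid: False for gid in gene_ids}
    for gi in planted:
        truth[gene_ids[gi]] = True
    return PairedExpressionMatrix(tumor, control, gene_ids, pair_ids), truth
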