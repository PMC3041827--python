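"""Negative-training-set construction.

Negatives are drawn only from protein families containing no positive
example; every eligible family contributes at least one protein and the
per-family counts are proportional to family size (largest-remainder
rounding). A protein belonging to any positive-containing family is
excluded from sampling entirely.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class FamilyTable:
    """Mapping protein id -> family id(s); a protein may sit in several
    families."""

    def __init__(self, pairs: list[tuple[str, str]]):
        if not pairs:
            raise ValueError("empty family table")
        seen = set()
        for pair in pairs:
            if pair in seen:
                raise ValueError(f"duplicate (protein, family) pair: {pair}")
            seen.add(pair)
        self.pairs = list(pairs)
        self.family_members: dict[str, set[str]] = {}
        self.protein_families: dict[str, set[str]] = {}
        for protein, family in pairs:
            self.family_members.setdefault(family, set()).add(protein)
            self.protein_families.setdefault(protein, set()).add(family)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FamilyTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError("family table needs columns protein_id, family_id")
        return cls(list(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.pairs, columns=["protein_id", "family_id"]).to_csv(
            path, sep="\t", index=False
        )


def eligible_families(table: FamilyTable, positives: set[str]) -> set[str]:
    """Families with zero members in the positive set."""
    eligible = {
        fam for fam, members in table.family_members.items()
        if not (members & positives)
    }
    if not eligible:
        raise ValueError("no family is free of positive training proteins")
    return eligible


def _eligible_pool(table: FamilyTable, positives: set[str]) -> dict[str, list[str]]:
    """Family -> sorted member list, after removing proteins touching any
    positive-containing family; multi-family proteins are counted once,
    in their largest eligible family (ties: lexicographically first)."""
    eligible = eligible_families(table, positives)
    pool: dict[str, list[str]] = {fam: [] for fam in eligible}
    for protein, fams in sorted(table.protein_families.items()):
        if not fams <= eligible:
            continue  # touches a contaminated family
        # largest eligible family wins; ties by lexicographic family id
        home = sorted(fams, key=lambda f: (-len(table.family_members[f]), f))[0]
        pool[home].append(protein)
    return {fam: sorted(members) for fam, members in pool.items() if members}


def allocate_proportional(sizes: dict[str, int], budget: int) -> dict[str, int]:
    """Per-family allocation: max(1, round(budget * size / total)), then a
    largest-remainder adjustment to hit the budget exactly, capped at the
    family size."""
    families = sorted(sizes)
    total = sum(sizes.values())
    if budget < len(families):
        raise ValueError(
            f"budget {budget} cannot cover at least one protein from each of "
            f"{len(families)} eligible families"
        )
    if budget > total:
        raise ValueError(f"budget {budget} exceeds the eligible pool of {total} proteins")
    quota = {f: budget * sizes[f] / total for f in families}
    alloc = {f: min(sizes[f], max(1, round(quota[f]))) for f in families}

    def key_inc(f):  # most under-allocated first
        return (-(quota[f] - alloc[f]), f)

    def key_dec(f):  # most over-allocated first
        return (-(alloc[f] - quota[f]), f)

    while sum(alloc.values()) < budget:
        candidates = [f for f in families if alloc[f] < sizes[f]]
        f = sorted(candidates, key=key_inc)[0]
        alloc[f] += 1
    while sum(alloc.values()) > budget:
        candidates = [f for f in families if alloc[f] > 1]
        f = sorted(candidates, key=key_dec)[0]
        alloc[f] -= 1
    return alloc


def sample_negatives(table: FamilyTable, positives: set[str], budget: int,
                     seed: int) -> list[str]:
    """Seeded negative-set draw of exactly `budget` proteins.

    The allocation is deterministic; only which members represent a family
    varies with the seed (uniform, without replacement).
    """
    pool = _eligible_pool(table, positives)
    sizes = {fam: len(members) for fam, members in pool.items()}
    alloc = allocate_proportional(sizes, budget)
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for fam in sorted(alloc):
        members = pool[fam]
        picked = rng.choice(len(members), size=alloc[fam], replace=False)
        chosen.extend(members[i] for i in sorted(picked))
    return chosen
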