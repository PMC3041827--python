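"""Ordered catalogue of feature values and vector assembly.

The default registry exposes 243 values split over the feature groups:

    aa_composition        20
    ctd                  147  (7 properties x 21)
    secondary_structure    3
    disorder               3
    signal_peptide         2
    membrane_motif         3
    glycosylation          2
    charge                 7
    protparam              5
    sequence_stats        51  (N/C-terminal composition + global stats)

The per-group breakdown is a repo convention (data-driven and
configurable); only the total of 243 is fixed by the default contract.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from . import compute
from .records import ProteinRecord
from .tables import CTD_PROPERTIES, STANDARD_AA

REGISTRY_VERSION = "uriexc-registry-243-v1"

DEFAULT_DIMENSION = 243


@dataclass(frozen=True)
class FeatureDescriptor:
    index: int
    name: str
    group: str
    scale_hint: str  # continuous | count | binary


def _ctd_names() -> list[str]:
    suffixes = (
        ["comp_g1", "comp_g2", "comp_g3", "trans_12", "trans_13", "trans_23"]
        + [f"dist_g{g}_{q}" for g in (1, 2, 3) for q in ("first", "q25", "q50", "q75", "last")]
    )
    return [f"ctd_{prop}_{s}" for prop in CTD_PROPERTIES for s in suffixes]


_GROUP_LAYOUT: list[tuple[str, list[str], str]] = [
    ("aa_composition", [f"frac_{aa}" for aa in STANDARD_AA], "continuous"),
    ("ctd", _ctd_names(), "continuous"),
    ("secondary_structure", ["ss_helix", "ss_strand", "ss_coil"], "continuous"),
    ("disorder", ["mean_fold_index", "frac_disordered", "longest_disordered_run"], "continuous"),
    ("signal_peptide", ["signal_score", "signal_call"], "continuous"),
    ("membrane_motif", ["tm_count", "beta_barrel_propensity", "tat_motif"], "continuous"),
    ("glycosylation", ["sequon_density", "st_density"], "continuous"),
    ("charge", [
        "net_charge", "charge_frac_K", "charge_frac_R", "charge_frac_H",
        "charge_frac_positive", "charge_frac_negative", "net_charge_per_residue",
    ], "continuous"),
    ("protparam", [
        "molecular_weight", "isoelectric_point", "gravy",
        "instability_index", "aliphatic_index",
    ], "continuous"),
    ("sequence_stats", list(compute.sequence_statistics("ACDEFGHIKLMNPQRSTVWYA").keys()), "continuous"),
]

_SCALE_OVERRIDES = {
    "signal_call": "binary",
    "tat_motif": "binary",
    "tm_count": "count",
}


class FeatureRegistry:
    """Immutable ordered list of feature descriptors plus the group
    evaluation plan used by :func:`compute_feature_vector`."""

    def __init__(self, layout: list[tuple[str, list[str], str]] | None = None,
                 version: str = REGISTRY_VERSION):
        layout = layout if layout is not None else _GROUP_LAYOUT
        self.version = version
        self.descriptors: list[FeatureDescriptor] = []
        self._group_slices: dict[str, slice] = {}
        idx = 0
        for group, names, default_hint in layout:
            start = idx
            for name in names:
                hint = _SCALE_OVERRIDES.get(name, default_hint)
                self.descriptors.append(FeatureDescriptor(idx, name, group, hint))
                idx += 1
            self._group_slices[group] = slice(start, idx)
        names_seen = [d.name for d in self.descriptors]
        if len(set(names_seen)) != len(names_seen):
            raise ValueError("duplicate feature names in registry layout")

    @property
    def dimension(self) -> int:
        return len(self.descriptors)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def group_slice(self, group: str) -> slice:
        return self._group_slices[group]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "dimension": self.dimension,
            "descriptors": [asdict(d) for d in self.descriptors],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def default_registry() -> FeatureRegistry:
    reg = FeatureRegistry()
    assert reg.dimension == DEFAULT_DIMENSION
    return reg


_GROUP_FUNCS: dict[str, Callable[[str], dict[str, float]]] = {
    "aa_composition": lambda s: {f"frac_{aa}": v for aa, v in compute.aa_composition(s).items()},
    "ctd": compute.ctd_features,
    "secondary_structure": lambda s: {
        f"ss_{k}": v for k, v in compute.secondary_structure_content(s).items()
    },
    "disorder": compute.disorder_features,
    "signal_peptide": compute.signal_peptide_features,
    "membrane_motif": compute.membrane_motif_features,
    "glycosylation": compute.glycosylation_features,
    "charge": compute.charge_features,
    "protparam": compute.protparam_features,
    "sequence_stats": compute.sequence_statistics,
}


def compute_feature_vector(record: ProteinRecord,
                           registry: FeatureRegistry | None = None) -> np.ndarray:
    """Assemble the full feature vector for one protein, in registry order.

    Deterministic: identical sequence gives a bit-identical vector.
    """
    registry = registry if registry is not None else default_registry()
    values: dict[str, float] = {}
    for group in registry._group_slices:
        values.update(_GROUP_FUNCS[group](record.sequence))
    vec = np.array([values[name] for name in registry.names], dtype=float)
    if not np.all(np.isfinite(vec)):
        bad = [registry.names[i] for i in np.where(~np.isfinite(vec))[0]]
        raise ValueError(f"non-finite feature values for {record.id}: {bad}")
    return vec


def compute_feature_matrix(records: list[ProteinRecord],
                           registry: FeatureRegistry | None = None) -> tuple[np.ndarray, list[str]]:
    """Stack feature vectors for a list of records; returns (matrix, ids)."""
    registry = registry if registry is not None else default_registry()
    mat = np.vstack([compute_feature_vector(r, registry) for r in records])
    return mat, [r.id for r in records]
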