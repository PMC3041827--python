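"""Tabular I/O shared across stages.

One tabular dialect everywhere: tab-delimited, header row, UTF-8, '.'
decimal — bit-exact diffability for tests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .selection import LabeledFeatureMatrix


def write_feature_matrix(path: str | Path, ids: list[str], matrix: np.ndarray,
                         feature_names: list[str]) -> None:
    df = pd.DataFrame(matrix, columns=feature_names)
    df.insert(0, "protein_id", ids)
    df.to_csv(path, sep="\t", index=False)


def read_feature_matrix(path: str | Path) -> tuple[list[str], np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "protein_id":
        raise ValueError("feature matrix must start with a protein_id column")
    ids = df["protein_id"].astype(str).tolist()
    names = list(df.columns[1:])
    return ids, df[names].to_numpy(dtype=float), names


def write_labels(path: str | Path, labels: dict[str, int]) -> None:
    pd.DataFrame(sorted(labels.items()), columns=["protein_id", "label"]).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    if not {"protein_id", "label"} <= set(df.columns):
        raise ValueError("labels file needs protein_id and label columns")
    labels = dict(zip(df["protein_id"], df["label"].astype(int)))
    bad = set(labels.values()) - {-1, 1}
    if bad:
        raise ValueError(f"labels must be +1/-1, found {sorted(bad)}")
    return labels


def labeled_matrix_from_files(matrix_path: str | Path, labels_path: str | Path,
                              registry_version: str = "") -> LabeledFeatureMatrix:
    ids, X, names = read_feature_matrix(matrix_path)
    labels = read_labels(labels_path)
    missing = [i for i in ids if i not in labels]
    if missing:
        raise ValueError(f"{len(missing)} proteins lack labels, e.g. {missing[:3]}")
    y = np.array([labels[i] for i in ids])
    return LabeledFeatureMatrix(matrix=X, labels=y, feature_names=names,
                                registry_version=registry_version)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_provenance(path: str | Path, config: dict, artifacts: list[str | Path]) -> None:
    from . import __version__
    from .features.registry import REGISTRY_VERSION

    block = {
        "tool_version": __version__,
        "registry_version": REGISTRY_VERSION,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "checksums": {str(Path(a).name): sha256_file(a) for a in artifacts},
    }
    Path(path).write_text(json.dumps(block, indent=1))
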