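"""Protein records and FASTA input."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .tables import NONSTANDARD_AA, STANDARD_AA

logger = logging.getLogger(__name__)

_VALID = set(STANDARD_AA) | NONSTANDARD_AA


class SequenceError(ValueError):
    """Raised for sequences violating the amino-acid alphabet contract."""


def normalize_sequence(sequence: str) -> str:
    """Uppercase and map nonstandard residue codes (B, J, O, U, Z, *) to X.

    Characters outside the amino-acid alphabet (digits, punctuation, gaps)
    are rejected. X residues stay in the sequence — window operations see
    them as neutral — but are excluded from composition denominators.
    """
    seq = sequence.upper().strip()
    if not seq:
        raise SequenceError("empty sequence")
    out = []
    for ch in seq:
        if ch in _VALID:
            out.append("X" if ch in NONSTANDARD_AA else ch)
        else:
            raise SequenceError(f"invalid residue character {ch!r}")
    return "".join(out)


@dataclass(frozen=True)
class ProteinRecord:
    """One identifier plus a normalized amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if not self.id:
            raise ValueError("empty protein id")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into a list of ProteinRecord, in file order.

    The header token before the first whitespace becomes the id. Lowercase
    bodies are uppercased. Empty files and duplicate ids are errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise ValueError(f"duplicate FASTA id: {rid}")
        seen.add(rid)
        records.append(ProteinRecord(rid, str(entry.seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
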