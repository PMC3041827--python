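"""Sequence-derived physicochemical feature operations.

Each operation is a pure function of (sequence, config). The default
registry concatenates the group outputs into a 243-value vector; see
`registry.py` for the exact layout. Scores produced here are desk-scale
approximations backed by the shipped tables in `tables.py`, not outputs of
the original third-party prediction servers.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .tables import (
    CTD_PROPERTIES,
    HELIX_PROPENSITY,
    HUMAN_BACKGROUND_FREQ,
    KYTE_DOOLITTLE,
    PKA_CTERM,
    PKA_NTERM,
    PKA_SIDECHAIN_ACIDIC,
    PKA_SIDECHAIN_BASIC,
    RESIDUE_MASS,
    SIMPLE_CHARGE,
    STANDARD_AA,
    STRAND_PROPENSITY,
    TURN_PROPENSITY,
    WATER_MASS,
)

logger = logging.getLogger(__name__)

_ = HUMAN_BACKGROUND_FREQ  # re-exported for the synthetic generator

# --- composition ---------------------------------------------------------


def aa_composition(sequence: str) -> dict[str, float]:
    """Fraction of each of the 20 standard residues, in alphabet order.

    X residues are excluded from the denominator; for a sequence of only
    X the composition is all zero.
    """
    counts = Counter(sequence)
    denom = sum(counts[aa] for aa in STANDARD_AA)
    if denom == 0:
        return {aa: 0.0 for aa in STANDARD_AA}
    return {aa: counts[aa] / denom for aa in STANDARD_AA}


# --- charge --------------------------------------------------------------


def henderson_hasselbalch_charge(sequence: str, pH: float = 7.0) -> float:
    """Net charge from the Henderson-Hasselbalch sum over ionizable side
    chains and the two termini, using the shipped pKa table."""
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH must lie in [0, 14], got {pH}")
    counts = Counter(sequence)
    charge = 1.0 / (1.0 + 10 ** (pH - PKA_NTERM))
    charge -= 1.0 / (1.0 + 10 ** (PKA_CTERM - pH))
    for aa, pka in PKA_SIDECHAIN_BASIC.items():
        charge += counts[aa] / (1.0 + 10 ** (pH - pka))
    for aa, pka in PKA_SIDECHAIN_ACIDIC.items():
        charge -= counts[aa] / (1.0 + 10 ** (pka - pH))
    return charge


def charge_features(sequence: str, pH: float = 7.0) -> dict[str, float]:
    """Net charge plus positive/negative residue fractions.

    Returns 7 values: net charge, K/R/H fractions, pooled positive
    fraction (K+R+H), pooled negative fraction (D+E), and net charge per
    residue.
    """
    comp = aa_composition(sequence)
    net = henderson_hasselbalch_charge(sequence, pH)
    return {
        "net_charge": net,
        "charge_frac_K": comp["K"],
        "charge_frac_R": comp["R"],
        "charge_frac_H": comp["H"],
        "charge_frac_positive": comp["K"] + comp["R"] + comp["H"],
        "charge_frac_negative": comp["D"] + comp["E"],
        "net_charge_per_residue": net / len(sequence),
    }


# --- classic protein parameters ------------------------------------------


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """pI by bisection on the Henderson-Hasselbalch charge curve."""
    lo, hi = 0.0, 14.0
    for _i in range(200):
        mid = 0.5 * (lo + hi)
        q = henderson_hasselbalch_charge(sequence, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def protparam_features(sequence: str) -> dict[str, float]:
    """Molecular weight, pI, GRAVY, instability index, aliphatic index.

    Molecular weight and GRAVY use the shipped tables; the instability
    index delegates to Biopython's dipeptide-weight implementation. X
    residues contribute zero mass/hydropathy and are dropped for the
    instability index.
    """
    clean = sequence.replace("X", "")
    n_std = len(clean)
    mw = sum(RESIDUE_MASS[aa] for aa in clean) + WATER_MASS
    gravy = (
        sum(KYTE_DOOLITTLE[aa] for aa in clean) / n_std if n_std else 0.0
    )
    if n_std >= 2:
        instability = ProteinAnalysis(clean).instability_index()
    else:
        logger.warning("instability index undefined for length-1 sequence; reporting 0")
        instability = 0.0
    comp = aa_composition(sequence)
    aliphatic = 100.0 * (
        comp["A"] + 2.9 * comp["V"] + 3.9 * (comp["I"] + comp["L"])
    )
    return {
        "molecular_weight": mw,
        "isoelectric_point": isoelectric_point(sequence),
        "gravy": gravy,
        "instability_index": instability,
        "aliphatic_index": aliphatic,
    }


# --- intrinsic disorder ---------------------------------------------------


def _fold_index_profile(sequence: str, window: int = 51) -> np.ndarray:
    """Per-residue fold-index score 2.785*<H> - |<R>| - 1.151 over a
    centred window, shrunk symmetrically at the sequence ends."""
    n = len(sequence)
    hyd = np.array([(KYTE_DOOLITTLE.get(aa, 0.0) + 4.5) / 9.0 for aa in sequence])
    chg = np.array([SIMPLE_CHARGE.get(aa, 0.0) for aa in sequence])
    half = window // 2
    scores = np.empty(n)
    for i in range(n):
        r = min(i, n - 1 - i, half)
        lo, hi = i - r, i + r + 1
        scores[i] = 2.785 * hyd[lo:hi].mean() - abs(chg[lo:hi].mean()) - 1.151
    return scores


def disorder_features(sequence: str, window: int = 51) -> dict[str, float]:
    """Mean fold-index, disordered fraction, longest disordered run
    (normalized by sequence length). Negative scores mark disorder."""
    scores = _fold_index_profile(sequence, window)
    disordered = scores < 0
    longest = 0
    run = 0
    for flag in disordered:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    return {
        "mean_fold_index": float(scores.mean()),
        "frac_disordered": float(disordered.mean()),
        "longest_disordered_run": longest / len(sequence),
    }


# --- secondary structure --------------------------------------------------


def secondary_structure_content(sequence: str) -> dict[str, float]:
    """Composition-based helix/strand/coil fractions.

    Mean conformational propensity per state, clipped to [0, 1] after
    scaling and renormalized to sum to 1.
    """
    std = [aa for aa in sequence if aa in HELIX_PROPENSITY]
    if not std:
        return {"helix": 1 / 3, "strand": 1 / 3, "coil": 1 / 3}
    h = sum(HELIX_PROPENSITY[aa] for aa in std) / len(std)
    s = sum(STRAND_PROPENSITY[aa] for aa in std) / len(std)
    t = sum(TURN_PROPENSITY[aa] for aa in std) / len(std)
    raw = np.clip([h, s, t], 0.0, None)
    total = raw.sum()
    frac = raw / total if total > 0 else np.full(3, 1 / 3)
    return {"helix": float(frac[0]), "strand": float(frac[1]), "coil": float(frac[2])}


# --- signal peptide -------------------------------------------------------

SIGNAL_SCORE_CUTOFF = 2.5
SIGNAL_NREGION_WEIGHT = 0.5


def signal_peptide_features(sequence: str, cutoff: float = SIGNAL_SCORE_CUTOFF) -> dict[str, float]:
    """Heuristic signal-peptide score over the first 45 residues.

    Best sliding h-region window (length 8-12) by mean Kyte-Doolittle
    hydrophobicity, plus a weighted count of basic residues (K/R) in the
    preceding n-region. Sequences shorter than 15 score 0 and are never
    called.
    """
    if len(sequence) < 15:
        return {"signal_score": 0.0, "signal_call": 0.0}
    prefix = sequence[:45]
    hyd = [KYTE_DOOLITTLE.get(aa, 0.0) for aa in prefix]
    best = -math.inf
    for length in range(8, 13):
        for start in range(0, len(prefix) - length + 1):
            h_mean = sum(hyd[start : start + length]) / length
            n_pos = sum(1 for aa in prefix[:start] if aa in "KR")
            best = max(best, h_mean + SIGNAL_NREGION_WEIGHT * n_pos)
    score = best if best > -math.inf else 0.0
    return {"signal_score": score, "signal_call": float(score >= cutoff)}


# --- membrane / motifs ----------------------------------------------------

TM_WINDOW = 19
TM_HYDROPHOBICITY_THRESHOLD = 1.6
TAT_MOTIF = re.compile(r"[ST]RR.[FL][LK]")


def membrane_motif_features(sequence: str) -> dict[str, float]:
    """Transmembrane-segment count, beta-barrel propensity, twin-arginine
    motif flag.

    TM count: disjoint 19-residue windows with mean hydropathy above the
    threshold, scanned greedily left to right. Beta-barrel propensity:
    max over 10-residue windows of |mean(even-offset KD) - mean(odd-offset
    KD)|. Twin-arginine flag: [ST]RR-x-[FL]-[LK] within the first 35
    residues.
    """
    hyd = [KYTE_DOOLITTLE.get(aa, 0.0) for aa in sequence]
    n = len(hyd)
    tm_count = 0
    i = 0
    while i + TM_WINDOW <= n:
        if sum(hyd[i : i + TM_WINDOW]) / TM_WINDOW >= TM_HYDROPHOBICITY_THRESHOLD:
            tm_count += 1
            i += TM_WINDOW
        else:
            i += 1
    barrel = 0.0
    if n >= 4:
        w = min(10, n)
        for start in range(0, n - w + 1):
            win = hyd[start : start + w]
            even = win[0::2]
            odd = win[1::2]
            barrel = max(barrel, abs(sum(even) / len(even) - sum(odd) / len(odd)))
    tat = 1.0 if TAT_MOTIF.search(sequence[:35]) else 0.0
    return {"tm_count": float(tm_count), "beta_barrel_propensity": barrel, "tat_motif": tat}


# --- glycosylation --------------------------------------------------------

_SEQUON = re.compile(r"N(?=[^PX][ST])")


def glycosylation_features(sequence: str) -> dict[str, float]:
    """N-glycosylation sequon count (N-X-[ST], X != P, overlapping) and
    S/T density as an O-glycosylation proxy."""
    count = len(_SEQUON.findall(sequence))
    comp = aa_composition(sequence)
    return {
        "sequon_count": float(count),
        "sequon_density": count / len(sequence),
        "st_density": comp["S"] + comp["T"],
    }


# --- composition / transition / distribution ------------------------------


def _ctd_one_property(groups: tuple[str, str, str], sequence: str) -> list[float]:
    encoded = []
    for aa in sequence:
        for gi, members in enumerate(groups):
            if aa in members:
                encoded.append(gi)
                break
    n = len(encoded)
    comp = [0.0, 0.0, 0.0]
    trans = [0.0, 0.0, 0.0]  # (0,1), (0,2), (1,2)
    dist = [0.0] * 15
    if n == 0:
        return comp + trans + dist
    counts = Counter(encoded)
    for g in range(3):
        comp[g] = counts[g] / n
    if n >= 2:
        pair_index = {(0, 1): 0, (0, 2): 1, (1, 2): 2}
        for a, b in zip(encoded, encoded[1:]):
            if a != b:
                trans[pair_index[(min(a, b), max(a, b))]] += 1
        trans = [t / (n - 1) for t in trans]
    if n >= 5:
        for g in range(3):
            positions = [i + 1 for i, e in enumerate(encoded) if e == g]
            if not positions:
                continue
            m = len(positions)
            for qi, q in enumerate((0.0, 0.25, 0.5, 0.75, 1.0)):
                idx = max(0, math.ceil(q * m) - 1)
                dist[5 * g + qi] = positions[idx] / n
    else:
        logger.warning("sequence shorter than 5 standard residues; CTD distribution set to 0")
    return comp + trans + dist


def ctd_features(sequence: str) -> dict[str, float]:
    """21 composition/transition/distribution values for each of the 7
    physicochemical partitions (147 values total).

    X residues are dropped before encoding. Distribution positions are
    1-based and normalized by the encoded length.
    """
    out: dict[str, float] = {}
    suffixes = (
        ["comp_g1", "comp_g2", "comp_g3", "trans_12", "trans_13", "trans_23"]
        + [f"dist_g{g}_{q}" for g in (1, 2, 3) for q in ("first", "q25", "q50", "q75", "last")]
    )
    for prop, groups in CTD_PROPERTIES.items():
        values = _ctd_one_property(groups, sequence)
        for suffix, value in zip(suffixes, values):
            out[f"ctd_{prop}_{suffix}"] = value
    return out


# --- padding block: length-normalized sequence statistics -----------------

NTERM_WINDOW = 25
CTERM_WINDOW = 25


def sequence_statistics(sequence: str) -> dict[str, float]:
    """51 auxiliary values: N-terminal (first 25 residues) composition,
    C-terminal (last 25) composition, and 11 global statistics."""
    out: dict[str, float] = {}
    nterm = aa_composition(sequence[:NTERM_WINDOW])
    cterm = aa_composition(sequence[-CTERM_WINDOW:])
    for aa in STANDARD_AA:
        out[f"nterm_frac_{aa}"] = nterm[aa]
    for aa in STANDARD_AA:
        out[f"cterm_frac_{aa}"] = cterm[aa]
    comp = aa_composition(sequence)
    fracs = np.array([comp[aa] for aa in STANDARD_AA])
    nonzero = fracs[fracs > 0]
    entropy = float(-(nonzero * np.log2(nonzero)).sum()) / math.log2(20) if nonzero.size else 0.0
    out["log10_length"] = math.log10(len(sequence))
    out["frac_tiny"] = sum(comp[aa] for aa in "AGCST")
    out["frac_small"] = sum(comp[aa] for aa in "AGCSTPDNV")
    out["frac_aliphatic"] = sum(comp[aa] for aa in "AVIL")
    out["frac_aromatic"] = sum(comp[aa] for aa in "FWY")
    out["frac_polar"] = sum(comp[aa] for aa in "STNQCYH")
    out["frac_hydrophobic"] = sum(comp[aa] for aa in "AVILMFWC")
    out["frac_charged"] = sum(comp[aa] for aa in "KRHDE")
    out["frac_proline_glycine"] = comp["P"] + comp["G"]
    out["max_residue_frac"] = float(fracs.max())
    out["composition_entropy"] = entropy
    return out
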