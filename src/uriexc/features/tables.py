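"""Shipped physicochemical coefficient tables.

All per-residue scores derive from these versioned tables rather than from
external prediction servers, so every feature value is reproducible offline.
"""

from __future__ import annotations

TABLES_VERSION = "uriexc-tables-1"

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# Ambiguity / nonstandard codes are mapped to 'X' and excluded from
# composition denominators (see validate_sequence).
NONSTANDARD_AA = set("BJOUZX*")

# Kyte-Doolittle hydropathy.
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

# Side-chain and terminal pKa values (EMBOSS set).
PKA_NTERM = 8.6
PKA_CTERM = 3.6
PKA_SIDECHAIN_ACIDIC = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
PKA_SIDECHAIN_BASIC = {"H": 6.5, "K": 10.8, "R": 12.5}

# Average residue masses (Da); water added once per chain.
RESIDUE_MASS = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155,
    "F": 147.1766, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "K": 128.1741, "L": 113.1594, "M": 131.1926, "N": 114.1038,
    "P": 97.1167, "Q": 128.1307, "R": 156.1875, "S": 87.0782,
    "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}
WATER_MASS = 18.01524

# Chou-Fasman conformational propensities (helix, strand, turn).
HELIX_PROPENSITY = {
    "A": 1.42, "C": 0.70, "D": 1.01, "E": 1.51, "F": 1.13,
    "G": 0.57, "H": 1.00, "I": 1.08, "K": 1.16, "L": 1.21,
    "M": 1.45, "N": 0.67, "P": 0.57, "Q": 1.11, "R": 0.98,
    "S": 0.77, "T": 0.83, "V": 1.06, "W": 1.08, "Y": 0.69,
}
STRAND_PROPENSITY = {
    "A": 0.83, "C": 1.19, "D": 0.54, "E": 0.37, "F": 1.38,
    "G": 0.75, "H": 0.87, "I": 1.60, "K": 0.74, "L": 1.30,
    "M": 1.05, "N": 0.89, "P": 0.55, "Q": 1.10, "R": 0.93,
    "S": 0.75, "T": 1.19, "V": 1.70, "W": 1.37, "Y": 1.47,
}
TURN_PROPENSITY = {
    "A": 0.66, "C": 1.19, "D": 1.46, "E": 0.74, "F": 0.60,
    "G": 1.56, "H": 0.95, "I": 0.47, "K": 1.01, "L": 0.59,
    "M": 0.60, "N": 1.56, "P": 1.52, "Q": 0.98, "R": 0.95,
    "S": 1.43, "T": 0.96, "V": 0.50, "W": 0.96, "Y": 1.14,
}

# Simple per-residue formal charge at neutral pH used by the fold-index
# style disorder score (H treated as neutral).
SIMPLE_CHARGE = {aa: 0.0 for aa in STANDARD_AA}
SIMPLE_CHARGE.update({"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0})

# Three-group alphabet partitions for composition/transition/distribution
# descriptors (the classical seven physicochemical attributes).
CTD_PROPERTIES: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MPSTHY"),
}

# Average human-proteome amino-acid frequencies (UniProt human reference
# proteome statistics, rounded); used as the synthetic background.
HUMAN_BACKGROUND_FREQ = {
    "A": 0.0702, "C": 0.0230, "D": 0.0473, "E": 0.0710, "F": 0.0365,
    "G": 0.0657, "H": 0.0263, "I": 0.0433, "K": 0.0573, "L": 0.0996,
    "M": 0.0213, "N": 0.0359, "P": 0.0631, "Q": 0.0477, "R": 0.0564,
    "S": 0.0833, "T": 0.0536, "V": 0.0597, "W": 0.0122, "Y": 0.0266,
}
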