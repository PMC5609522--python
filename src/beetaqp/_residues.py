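"""Residue-level constant tables shared across modules.

Masses are ExPASy-style average isotopic residue masses (amino acid minus
one water); hydropathy is the Kyte-Doolittle scale; pKa sets cover the
EMBOSS and Bjellqvist conventions for isoelectric-point estimation.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Average residue masses in Da (peptide-bond residues; add one water for a
#: free peptide).
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MASS = 18.01524

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: pKa values for ionizable groups. Keys: "nterm", "cterm" and the residue
#: one-letter codes that titrate. Positive groups: nterm, K, R, H; negative:
#: cterm, D, E, C, Y.
PKA_SETS: dict[str, dict[str, float]] = {
    "emboss": {
        "nterm": 8.6, "cterm": 3.6,
        "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
        "K": 10.8, "R": 12.5, "Y": 10.1,
    },
    "bjellqvist": {
        "nterm": 7.5, "cterm": 3.55,
        "C": 9.0, "D": 4.05, "E": 4.45, "H": 5.98,
        "K": 10.0, "R": 12.0, "Y": 10.0,
    },
}

POSITIVE_GROUPS = ("K", "R", "H")
NEGATIVE_GROUPS = ("D", "E", "C", "Y")


def validate_sequence(sequence: str) -> str:
    """Upper-case and validate a protein sequence.

    Raises ``ValueError`` naming the offending characters if any residue is
    outside the 20 canonical amino acids.
    """
    seq = sequence.strip().upper()
    bad = sorted({c for c in seq if c not in AMINO_ACIDS})
    if bad:
        raise ValueError(f"invalid residue character(s): {''.join(bad)}")
    return seq
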