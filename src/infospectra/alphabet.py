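"""Nucleotide alphabet, integer coding and IUPAC ambiguity table."""

from __future__ import annotations

import numpy as np

NUCLEOTIDES = "ACGT"
GAP = "-"

#: code order A=0, C=1, G=2, T=3; gap coded 4 where gaps are permitted
CODE = {c: i for i, c in enumerate(NUCLEOTIDES)}
CODE_WITH_GAP = {**CODE, GAP: 4}

#: IUPAC nucleotide ambiguity codes -> the set of nucleotides each permits
IUPAC_AMBIGUITY = {
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

VALID_RESIDUES = frozenset(NUCLEOTIDES) | {GAP} | frozenset(IUPAC_AMBIGUITY)

_DECODE = np.array(list(NUCLEOTIDES))


def encode(residues: str, allow_gap: bool = False) -> np.ndarray:
    """Encode an A/C/G/T(/-) string as an int8 array (A=0..T=3, '-'=4)."""
    table = CODE_WITH_GAP if allow_gap else CODE
    try:
        return np.fromiter((table[c] for c in residues), dtype=np.int8, count=len(residues))
    except KeyError as exc:  # pragma: no cover - message path
        raise ValueError(f"invalid residue {exc.args[0]!r} for encoding") from None


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for gap-free code arrays."""
    return "".join(_DECODE[np.asarray(codes)])
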