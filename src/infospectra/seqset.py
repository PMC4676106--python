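"""Reading, filtering and normalising species-grouped aligned FASTA.

The preprocessing contract: starting from aligned sequences over
{A,C,G,T,-} plus IUPAC ambiguity codes, produce gap-free alignments over
{A,C,G,T} only, via

1. blacklist purge (drop records with undesirable words in the header),
2. column trimming at a maximum vertical-gap fraction ("mincut" at 10 %,
   "maxmer" at 40 % under the defaults),
3. dropping sequences whose own (horizontal) gap fraction is too high,
4. replacement of ambiguity codes by the column consensus among the
   nucleotides the code permits,
5. replacement of remaining gaps by the column consensus nucleotide.

Every information-spectrum operation downstream requires the gap-free
{A,C,G,T} output of this module.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .alphabet import (
    GAP,
    IUPAC_AMBIGUITY,
    NUCLEOTIDES,
    VALID_RESIDUES,
    encode,
)

__all__ = [
    "SequenceRecord",
    "AlignmentSet",
    "TrimPolicy",
    "read_species_fasta",
    "purge_records",
    "drop_blacklisted",
    "replace_ambiguities",
    "trim_columns",
    "trim_columns_pooled",
    "drop_gappy_sequences",
    "consensus_fill",
    "apply_species_cutoff",
    "write_fasta",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence of an alignment: identifier, free-text description, residues."""

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty residues")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue {sorted(bad)[0]!r}"
            )

    @property
    def gap_fraction(self) -> float:
        return self.residues.count(GAP) / len(self.residues)


@dataclass
class AlignmentSet:
    """The aligned sequences of one species."""

    species: str
    records: list[SequenceRecord]
    aligned: bool = True

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"species {self.species!r}: no records")
        if self.aligned:
            lengths = {len(r.residues) for r in self.records}
            if len(lengths) > 1:
                raise ValueError(
                    f"species {self.species!r}: unequal aligned lengths {sorted(lengths)}"
                )

    @property
    def n(self) -> int:
        """Number of sequences."""
        return len(self.records)

    @property
    def L(self) -> int:
        """Alignment length (columns)."""
        return len(self.records[0].residues)

    def to_codes(self, allow_gap: bool = False) -> np.ndarray:
        """(n, L) int8 matrix; raises if residues fall outside the coded alphabet."""
        return np.vstack([encode(r.residues, allow_gap=allow_gap) for r in self.records])

    def with_residues(self, matrix: Iterable[str]) -> "AlignmentSet":
        recs = [replace(r, residues=s) for r, s in zip(self.records, matrix)]
        return AlignmentSet(self.species, recs, aligned=self.aligned)


@dataclass(frozen=True)
class TrimPolicy:
    """Gap-control thresholds (fractions in [0, 1]).

    ``max_vertical_gaps_mincut`` / ``max_vertical_gaps_maxmer`` bound the
    per-column gap fraction for the short ("mincut") and long ("maxmer")
    alignment variants; ``max_horizontal_gaps`` bounds the per-sequence gap
    fraction.
    """

    max_vertical_gaps_mincut: float = 0.10
    max_vertical_gaps_maxmer: float = 0.40
    max_horizontal_gaps: float = 0.40

    def __post_init__(self) -> None:
        for name in (
            "max_vertical_gaps_mincut",
            "max_vertical_gaps_maxmer",
            "max_horizontal_gaps",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


# ---------------------------------------------------------------------------
# ingestion


def _records_from_handle(path: Path) -> list[SequenceRecord]:
    recs = [
        SequenceRecord(r.id, r.description, str(r.seq).upper())
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not recs:
        raise ValueError(f"{path}: empty or unparsable FASTA")
    return recs


def read_species_fasta(
    path: str | Path,
    species_from: str = "stem",
    header_regex: str | None = None,
    aligned: bool = True,
) -> dict[str, AlignmentSet]:
    """Read species-grouped FASTA into one :class:`AlignmentSet` per species.

    Parameters
    ----------
    path:
        A FASTA file, or a directory of ``*.fasta`` / ``*.fa`` files
        (one file per species).
    species_from:
        ``"stem"`` — species named after the file stem; ``"header"`` —
        species parsed from each record description via ``header_regex``
        (first capture group).
    aligned:
        When true (default) mixed-length records within a species are an
        error; raw mode (``False``) postpones the check.
    """
    path = Path(path)
    grouped: dict[str, list[SequenceRecord]] = {}
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".fasta", ".fa", ".fna"))
        if not files:
            raise ValueError(f"{path}: no FASTA files found")
        for f in files:
            grouped.setdefault(f.stem, []).extend(_records_from_handle(f))
    else:
        recs = _records_from_handle(path)
        if species_from == "stem":
            grouped[path.stem] = recs
        elif species_from == "header":
            if not header_regex:
                raise ValueError("species_from='header' requires header_regex")
            rx = re.compile(header_regex)
            for r in recs:
                m = rx.search(r.description)
                if not m:
                    raise ValueError(f"record {r.id!r}: header does not match species rule")
                grouped.setdefault(m.group(1), []).append(r)
        else:
            raise ValueError(f"unknown species_from rule {species_from!r}")
    return {sp: AlignmentSet(sp, recs, aligned=aligned) for sp, recs in grouped.items()}


# ---------------------------------------------------------------------------
# purging


def drop_blacklisted(a: AlignmentSet, blacklist: Iterable[str]) -> AlignmentSet:
    """Remove records whose description contains any blacklist word
    (case-insensitive substring)."""
    words = [w.lower() for w in blacklist]
    kept = [
        r for r in a.records
        if not any(w in r.description.lower() for w in words)
    ]
    if not kept:
        raise ValueError(f"empty species after purge: {a.species!r}")
    return AlignmentSet(a.species, kept, aligned=a.aligned)


def replace_ambiguities(a: AlignmentSet) -> AlignmentSet:
    """Resolve IUPAC ambiguity codes by column consensus.

    Each code is replaced by the most frequent column nucleotide among the
    set the code permits; if none of the permitted nucleotides occurs in
    the column, the alphabetically first permitted one is used.
    """
    cols = [r.residues for r in a.records]
    matrix = [list(s) for s in cols]
    L = a.L
    for j in range(L):
        column = [row[j] for row in matrix]
        if not any(c in IUPAC_AMBIGUITY for c in column):
            continue
        counts = {nt: 0 for nt in NUCLEOTIDES}
        for c in column:
            if c in counts:
                counts[c] += 1
        for i, c in enumerate(column):
            if c in IUPAC_AMBIGUITY:
                allowed = IUPAC_AMBIGUITY[c]
                best = max(allowed, key=lambda nt: (counts[nt], -ord(nt)))
                if counts[best] == 0:
                    best = min(allowed)
                matrix[i][j] = best
    return a.with_residues("".join(row) for row in matrix)


def purge_records(a: AlignmentSet, blacklist: Iterable[str] = ()) -> AlignmentSet:
    """Blacklist purge followed by ambiguity resolution; output ∈ {A,C,G,T,-}."""
    return replace_ambiguities(drop_blacklisted(a, blacklist))


# ---------------------------------------------------------------------------
# trimming


def _gap_matrix(a: AlignmentSet) -> np.ndarray:
    return np.array([[c == GAP for c in r.residues] for r in a.records], dtype=bool)


def _delete_columns(a: AlignmentSet, keep: np.ndarray) -> AlignmentSet:
    if not keep.any():
        raise ValueError(f"species {a.species!r}: all columns trimmed")
    idx = np.flatnonzero(keep)
    return a.with_residues(
        "".join(r.residues[j] for j in idx) for r in a.records
    )


def trim_columns(a: AlignmentSet, max_gap_fraction: float) -> AlignmentSet:
    """Delete every column whose gap fraction exceeds ``max_gap_fraction``."""
    gaps = _gap_matrix(a)
    keep = gaps.mean(axis=0) <= max_gap_fraction
    return _delete_columns(a, keep)


def trim_columns_pooled(
    sets: Mapping[str, AlignmentSet], max_gap_fraction: float
) -> dict[str, AlignmentSet]:
    """Trim the same columns in every species, judging gap fractions on the
    pooled cross-species alignment (all species share coordinates)."""
    lengths = {a.L for a in sets.values()}
    if len(lengths) != 1:
        raise ValueError(f"pooled trimming requires equal lengths, got {sorted(lengths)}")
    pooled = np.vstack([_gap_matrix(a) for a in sets.values()])
    keep = pooled.mean(axis=0) <= max_gap_fraction
    return {sp: _delete_columns(a, keep) for sp, a in sets.items()}


def drop_gappy_sequences(a: AlignmentSet, max_horizontal_gap_fraction: float) -> AlignmentSet:
    """Remove records whose own gap fraction exceeds the threshold."""
    kept = [r for r in a.records if r.gap_fraction <= max_horizontal_gap_fraction]
    if not kept:
        raise ValueError(f"species {a.species!r}: all sequences dropped as gappy")
    return AlignmentSet(a.species, kept, aligned=a.aligned)


# ---------------------------------------------------------------------------
# consensus fill


def consensus_fill(a: AlignmentSet) -> AlignmentSet:
    """Replace every gap by the most frequent non-gap nucleotide of its column.

    Ties break alphabetically (A < C < G < T). A column consisting only of
    gaps has no consensus and is an error.
    """
    codes = a.to_codes(allow_gap=True)
    n, L = codes.shape
    counts = np.zeros((L, 4), dtype=np.int64)
    for m in range(4):
        counts[:, m] = (codes == m).sum(axis=0)
    if (counts.sum(axis=1) == 0).any():
        j = int(np.flatnonzero(counts.sum(axis=1) == 0)[0])
        raise ValueError(f"species {a.species!r}: column {j + 1} is all gaps, no consensus")
    winner = counts.argmax(axis=1)  # argmax takes the lowest code on ties = alphabetical
    filled = codes.copy()
    gap_rows, gap_cols = np.nonzero(codes == 4)
    filled[gap_rows, gap_cols] = winner[gap_cols]
    from .alphabet import decode

    return a.with_residues(decode(row) for row in filled)


def apply_species_cutoff(
    sets: Mapping[str, AlignmentSet], cutoff: int
) -> dict[str, AlignmentSet]:
    """Retain only species with at least ``cutoff`` sequences."""
    return {sp: a for sp, a in sets.items() if a.n >= cutoff}


def write_fasta(a: AlignmentSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in a.records
    ]
    SeqIO.write(bio, str(path), "fasta")
    return path
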