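"""Synthetic species sequence sets with controlled information structure.

The generator emulates the data regime of a highly conserved locus
sampled per species: a conserved background (most columns have zero
vertical entropy), a handful of planted polymorphic columns, optional
covarying column pairs (the vertical-MI signal), an optional periodic
motif (the horizontal-MI signal), and sprinkled gaps/ambiguity codes so
the preprocessing stages have work to do. Everything is deterministic
under the spec's seed; each species s draws from the substream
``default_rng([seed, s])``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .alphabet import IUPAC_AMBIGUITY, decode
from .seqset import AlignmentSet, SequenceRecord, write_fasta

__all__ = ["FixtureSpec", "conserved_locus_spec", "generate", "write_fixture"]

#: fixed bijection used for planted covariation (Watson–Crick-like pairing)
BIJECTION = np.array([3, 2, 1, 0])  # A<->T, C<->G

_AMBIG_CODES = sorted(IUPAC_AMBIGUITY)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study.

    ``polymorphic_columns`` is a sequence of ``(position, minor_allele_fraction)``;
    ``covarying_pairs`` of ``(i, j, coupling)`` with coupling ∈ [0, 1];
    ``periodic_motif`` an optional ``(motif, rate)`` writing the motif into
    period-aligned blocks of the species background with the given
    probability per block (rate 1 → perfectly periodic background).
    Positions are 0-based and must not collide between planted features.
    """

    n_species: int = 3
    n_per_species: int = 12
    L: int = 300
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    polymorphic_columns: tuple[tuple[int, float], ...] = ()
    covarying_pairs: tuple[tuple[int, int, float], ...] = ()
    periodic_motif: tuple[str, float] | None = None
    gap_rate: float = 0.0
    ambiguity_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_per_species < 1 or self.L < 1:
            raise ValueError("n_species, n_per_species and L must be >= 1")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        used: set[int] = set()
        for pos, maf in self.polymorphic_columns:
            if not 0 <= pos < self.L:
                raise ValueError(f"polymorphic column {pos} outside [0, L)")
            if not 0.0 <= maf <= 1.0:
                raise ValueError(f"minor-allele fraction {maf} outside [0, 1]")
            if pos in used:
                raise ValueError(f"overlapping planted features at column {pos}")
            used.add(pos)
        for i, j, c in self.covarying_pairs:
            if i == j:
                raise ValueError("covarying pair must use two distinct columns")
            for pos in (i, j):
                if not 0 <= pos < self.L:
                    raise ValueError(f"covarying column {pos} outside [0, L)")
                if pos in used:
                    raise ValueError(f"overlapping planted features at column {pos}")
                used.add(pos)
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coupling {c} outside [0, 1]")
        for rate in (self.gap_rate, self.ambiguity_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.periodic_motif is not None:
            motif, rate = self.periodic_motif
            if len(motif) < 3 or set(motif) - set("ACGT"):
                raise ValueError("motif must be >= 3 letters over ACGT")
            if not 0.0 <= rate <= 1.0:
                raise ValueError("motif rate must be in [0, 1]")


def conserved_locus_spec(seed: int = 0, n_species: int = 3) -> FixtureSpec:
    """Default study conditions: a conserved 300-bp locus, 12 sequences per
    species, ~4 % polymorphic columns at low minor-allele fractions (so the
    median vertical entropy is 0), one strongly covarying column pair and a
    weak 12-periodic motif giving a small but nonzero horizontal signal,
    plus light gap/ambiguity contamination exercising the preprocessing."""
    return FixtureSpec(
        n_species=n_species,
        n_per_species=12,
        L=300,
        polymorphic_columns=(
            (23, 0.2), (57, 0.35), (91, 0.15), (140, 0.25),
            (181, 0.3), (222, 0.2), (263, 0.4), (287, 0.1),
        ),
        covarying_pairs=((110, 170, 1.0),),
        periodic_motif=("ACGTTGCAACGT", 0.6),
        gap_rate=0.02,
        ambiguity_rate=0.002,
        seed=seed,
    )


def _species_reference(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    ref = rng.choice(4, size=spec.L, p=spec.base_composition)
    if spec.periodic_motif is not None:
        motif, rate = spec.periodic_motif
        mcodes = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[c] for c in motif])
        m = len(motif)
        for start in range(0, spec.L - m + 1, m):
            if rng.random() < rate:
                ref[start : start + m] = mcodes
    return ref


def generate(spec: FixtureSpec) -> dict[str, AlignmentSet]:
    """Generate one raw (possibly gapped/ambiguous) alignment per species.

    All species share one background reference (they model homologous
    copies of the same locus, which is what lets the pooled cross-species
    trimming share columns); each species' own substream then realises
    the polymorphisms, covariation draws, gaps and ambiguities. Species
    from one call are therefore samples of the same generating process,
    while calls with different specs produce structurally different data.
    """
    ref = _species_reference(spec, np.random.default_rng([spec.seed, 0]))
    sets: dict[str, AlignmentSet] = {}
    for s in range(spec.n_species):
        rng = np.random.default_rng([spec.seed, s + 1])
        name = f"sp{s + 1:02d}"
        mat = np.tile(ref, (spec.n_per_species, 1))
        for pos, maf in spec.polymorphic_columns:
            minor = (ref[pos] + 1 + rng.integers(3)) % 4
            hits = rng.random(spec.n_per_species) < maf
            mat[hits, pos] = minor
        for i, j, c in spec.covarying_pairs:
            x = rng.integers(0, 4, size=spec.n_per_species)
            mat[:, i] = x
            coupled = rng.random(spec.n_per_species) < c
            mat[:, j] = np.where(
                coupled, BIJECTION[x], rng.integers(0, 4, size=spec.n_per_species)
            )
        rows = [decode(row) for row in mat]
        if spec.gap_rate > 0 or spec.ambiguity_rate > 0:
            noisy = []
            for row in rows:
                chars = list(row)
                u = rng.random(spec.L)
                for t in range(spec.L):
                    if u[t] < spec.gap_rate:
                        chars[t] = "-"
                    elif u[t] < spec.gap_rate + spec.ambiguity_rate:
                        chars[t] = _AMBIG_CODES[rng.integers(len(_AMBIG_CODES))]
                noisy.append("".join(chars))
            rows = noisy
        records = [
            SequenceRecord(
                id=f"{name}_{r + 1:03d}",
                description=f"{name}_{r + 1:03d} simulated locus copy {r + 1}",
                residues=row,
            )
            for r, row in enumerate(rows)
        ]
        sets[name] = AlignmentSet(name, records)
    return sets


def write_fixture(
    sets: dict[str, AlignmentSet], outdir: str | Path, spec: FixtureSpec | None = None
) -> list[Path]:
    """Write one FASTA per species plus, if given, the generating
    parameters as a plain-text key=value provenance file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = [write_fasta(a, outdir / f"{sp}.fasta") for sp, a in sorted(sets.items())]
    if spec is not None:
        lines = [f"{k} = {v!r}" for k, v in asdict(spec).items()]
        (outdir / "fixture_spec.txt").write_text("\n".join(lines) + "\n")
        paths.append(outdir / "fixture_spec.txt")
    return paths
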