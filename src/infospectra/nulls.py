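"""Null models: shuffled and random sequence sets and their spectra bands.

Real spectra are compared against two kinds of noise: per-sequence
residue shuffles (preserving each sequence's nucleotide content exactly)
and fully random i.i.d. uniform draws (composition tending to 25 % per
nucleotide). Replicated null spectra yield per-bin empirical confidence
bands (mean ± 2 sd).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import decode
from .seqset import AlignmentSet, SequenceRecord
from .spectra import (
    MIMatrix,
    Spectrum,
    SpectrumConfig,
    hmi_spectrum,
    vertical_entropy_spectrum,
    vmi_matrix,
)

__all__ = ["NullConfig", "NullBand", "shuffle_set", "random_set", "null_spectrum_band"]


@dataclass(frozen=True)
class NullConfig:
    """Null-model settings: ``mode`` is ``"shuffled"`` or ``"random"``;
    replicate r draws from a stream seeded with ``seed + r``."""

    mode: str = "shuffled"
    seed: int = 0
    replicates: int = 20

    def __post_init__(self) -> None:
        if self.mode not in ("shuffled", "random"):
            raise ValueError(f"mode must be 'shuffled' or 'random', got {self.mode!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class NullBand:
    """Per-bin null mean and 95 % empirical band (mean ± 2 sd over replicates)."""

    kind: str
    mode: str
    index: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    unit: str
    replicates: int
    meta: dict = field(default_factory=dict)

    @property
    def lo(self) -> np.ndarray:
        return self.mean - 2.0 * self.sd

    @property
    def hi(self) -> np.ndarray:
        return self.mean + 2.0 * self.sd

    def summary(self) -> dict[str, float]:
        return {
            "mean": float(self.mean.mean()),
            "sd": float(self.mean.std(ddof=1)) if len(self.mean) > 1 else 0.0,
            "median": float(np.median(self.mean)),
        }


def shuffle_set(a: AlignmentSet, seed: int) -> AlignmentSet:
    """Permute each sequence's residues independently and uniformly.

    Per-sequence nucleotide composition is exactly preserved; n and L are
    unchanged; deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    codes = a.to_codes()
    shuffled = [decode(rng.permutation(row)) for row in codes]
    return a.with_residues(shuffled)


def random_set(n: int, L: int, seed: int, species: str = "random") -> AlignmentSet:
    """i.i.d. uniform A/C/G/T alignment of ``n`` sequences of length ``L``."""
    if n < 1 or L < 1:
        raise ValueError("n and L must be >= 1")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=(n, L))
    records = [
        SequenceRecord(f"{species}_{r + 1:03d}", f"{species} draw {r + 1}", decode(row))
        for r, row in enumerate(codes)
    ]
    return AlignmentSet(species, records)


def _null_replicate(a: AlignmentSet, cfg: NullConfig, r: int) -> AlignmentSet:
    seed = cfg.seed + r
    if cfg.mode == "shuffled":
        return shuffle_set(a, seed)
    return random_set(a.n, a.L, seed, species=a.species)


def _spectrum_values(a: AlignmentSet, kind: str, scfg: SpectrumConfig):
    if kind == "VH":
        s = vertical_entropy_spectrum(a, scfg)
        return s.index, s.values
    if kind == "HMI":
        s = hmi_spectrum(a, scfg)
        return s.index, s.values
    if kind == "VMI":
        m = vmi_matrix(a, scfg)
        return np.arange(1, len(m) + 1), m.values
    raise ValueError(f"unknown spectrum kind {kind!r}")


def null_spectrum_band(
    a: AlignmentSet,
    kind: str,
    cfg: NullConfig,
    scfg: SpectrumConfig = SpectrumConfig(),
) -> NullBand:
    """Replicated null spectra of ``a``: per-bin mean and ± 2 sd band.

    For ``kind="VMI"`` bins are the flattened upper-triangle cells in the
    fixed row-major order. Requires at least 2 replicates for the band to
    be defined.
    """
    if cfg.replicates < 2:
        raise ValueError("null band needs replicates >= 2")
    stack = []
    index = None
    for r in range(cfg.replicates):
        null = _null_replicate(a, cfg, r)
        index, vals = _spectrum_values(null, kind, scfg)
        stack.append(vals)
    arr = np.vstack(stack)
    return NullBand(
        kind=kind,
        mode=cfg.mode,
        index=index,
        mean=arr.mean(axis=0),
        sd=arr.std(axis=0, ddof=1),
        unit=scfg.unit,
        replicates=cfg.replicates,
        meta={"species": a.species, "nol": scfg.nol, "bias_correction": scfg.bias_correction},
    )
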