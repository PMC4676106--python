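"""Information spectra of aligned DNA: vertical entropy (VH), vertical
mutual information (VMI) and horizontal mutual information (HMI).

All estimators work on plug-in (maximum-likelihood) probabilities with the
convention 0·log 0 = 0, optionally applying the first-order finite-sample
bias correction of Roulston together with his delta-method standard
errors:

    H_corr  = H_plugin  + (M̂ − 1) / (2N)                      [nat]
    MI_corr = MI_plugin − (M̂_xy − M̂_x − M̂_y + 1) / (2N)       [nat]

    Var(H)  = (1/N) [ Σ p_m (ln p_m)²  − H² ]
    Var(MI) = (1/N) [ Σ p_mn (ln p_mn − ln p_m − ln p_n)² − MI² ]

where M̂ counts states with nonzero observed probability and N is the
number of samples behind the counts (sequences for vertical spectra,
position pairs for HMI).

The token being counted is an NOL-letter word (NOL ≥ 1, alphabet size
4^NOL); all demonstrations in the companion docs use NOL = 1. Internal
unit is the nat; "mnat" (millinat) and "MER" (entropy of an equiprobable
4^NOL-word distribution ≡ 1) are presentation conversions.

Coordinates: function arguments (positions i, j) are 0-based; reported
spectrum/matrix indices are 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Iterable

import numpy as np

from .alphabet import encode
from .seqset import AlignmentSet, SequenceRecord

__all__ = [
    "LN4",
    "SpectrumConfig",
    "Spectrum",
    "MIMatrix",
    "JointDistribution",
    "column_entropy",
    "vertical_entropy_spectrum",
    "joint_distribution_vertical",
    "mutual_information",
    "vmi_matrix",
    "hmi_single_sequence",
    "hmi_spectrum",
]

LN4 = math.log(4.0)

_UNITS = ("nat", "mnat", "MER")


@dataclass(frozen=True)
class SpectrumConfig:
    """Estimation settings shared by all spectra.

    Parameters
    ----------
    nol:
        Word width in letters (NOL ≥ 1); co-occurrence is counted between
        non-overlapping NOL-letter words.
    bias_correction:
        Apply the first-order Roulston correction (see module docstring).
    unit:
        Output unit: ``nat`` (natural log), ``mnat`` (= 1000 nat) or
        ``MER`` (= nat / (NOL·ln 4), so an equiprobable word distribution
        has entropy 1).
    """

    nol: int = 1
    bias_correction: bool = False
    unit: str = "nat"

    def __post_init__(self) -> None:
        if self.nol < 1:
            raise ValueError(f"nol must be >= 1, got {self.nol}")
        if self.unit not in _UNITS:
            raise ValueError(f"unit must be one of {_UNITS}, got {self.unit!r}")

    @property
    def unit_factor(self) -> float:
        """Multiplier converting a nat value into ``unit``."""
        if self.unit == "nat":
            return 1.0
        if self.unit == "mnat":
            return 1000.0
        return 1.0 / (self.nol * LN4)


@dataclass
class Spectrum:
    """A one-dimensional information profile with per-bin standard errors.

    ``kind`` is ``"VH"`` (index = 1-based word start position) or
    ``"HMI"`` (index = lag k).
    """

    kind: str
    index: np.ndarray
    values: np.ndarray
    se: np.ndarray
    unit: str = "nat"
    species: str | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)

    def summary(self) -> dict[str, float]:
        v = np.asarray(self.values, dtype=float)
        return {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
            "median": float(np.median(v)),
        }

    def in_unit(self, unit: str, nol: int = 1) -> "Spectrum":
        f = SpectrumConfig(nol=nol, unit=unit).unit_factor / SpectrumConfig(
            nol=nol, unit=self.unit
        ).unit_factor
        return _dc_replace(
            self, values=self.values * f, se=self.se * f, unit=unit
        )


@dataclass
class MIMatrix:
    """Vertical mutual information over all ordered position pairs i < j
    (non-overlapping word windows: j ≥ i + NOL), stored condensed in
    row-major (i, j) order. ``i``/``j`` are 0-based internally."""

    i: np.ndarray
    j: np.ndarray
    values: np.ndarray
    se: np.ndarray
    n_positions: int
    nol: int = 1
    unit: str = "nat"
    species: str | None = None

    def __len__(self) -> int:
        return len(self.values)

    @property
    def max_value(self) -> float:
        return float(self.values.max())

    @property
    def argmax(self) -> tuple[int, int]:
        """(i, j) of the maximum cell, 1-based as reported in figures."""
        k = int(self.values.argmax())
        return int(self.i[k]) + 1, int(self.j[k]) + 1

    def to_dense(self) -> np.ndarray:
        """Symmetric (P, P) matrix with NaN where no pair is defined."""
        d = np.full((self.n_positions, self.n_positions), np.nan)
        d[self.i, self.j] = self.values
        d[self.j, self.i] = self.values
        return d

    def summary(self) -> dict[str, float]:
        v = self.values
        return {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
            "median": float(np.median(v)),
        }


@dataclass
class JointDistribution:
    """Counts of ordered word pairs (m, n) over a 4^NOL × 4^NOL table."""

    counts: np.ndarray
    nol: int = 1

    def __post_init__(self) -> None:
        k = 4 ** self.nol
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be ({k}, {k}) for nol={self.nol}")
        if self.counts.sum() <= 0:
            raise ValueError("joint distribution has no observations")

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def p_mn(self) -> np.ndarray:
        return self.counts / self.N

    @property
    def p_m(self) -> np.ndarray:
        return self.p_mn.sum(axis=1)

    @property
    def p_n(self) -> np.ndarray:
        return self.p_mn.sum(axis=0)


# ---------------------------------------------------------------------------
# scalar estimators (nat-internal)


def _entropy_nat(counts: np.ndarray, bias_correction: bool) -> tuple[float, float]:
    """Plug-in entropy (optionally bias corrected) and Roulston SE, in nat."""
    counts = np.asarray(counts, dtype=float)
    N = counts.sum()
    if N <= 0:
        raise ValueError("empty column")
    p = counts[counts > 0] / N
    logp = np.log(p)
    h = float(-(p * logp).sum()) + 0.0  # normalise -0.0
    var = max(0.0, float((p * logp**2).sum() - h * h)) / N
    se = math.sqrt(var)
    if bias_correction:
        h += (len(p) - 1) / (2.0 * N)
    return h, se


def _mi_nat(counts2d: np.ndarray, bias_correction: bool) -> tuple[float, float]:
    """Plug-in MI (optionally bias corrected) and Roulston SE, in nat."""
    c = np.asarray(counts2d, dtype=float)
    N = c.sum()
    p = c / N
    pm = p.sum(axis=1)
    pn = p.sum(axis=0)
    nz = p > 0
    term = np.zeros_like(p)
    term[nz] = np.log(p[nz]) - np.log((pm[:, None] * pn[None, :])[nz])
    mi = float((p * term).sum())
    var = max(0.0, float((p * term**2).sum() - mi * mi)) / N
    se = math.sqrt(var)
    if bias_correction:
        m_xy = int(nz.sum())
        m_x = int((pm > 0).sum())
        m_y = int((pn > 0).sum())
        mi -= (m_xy - m_x - m_y + 1) / (2.0 * N)
    return mi, se


# ---------------------------------------------------------------------------
# word encoding


def _word_codes(codes: np.ndarray, nol: int) -> np.ndarray:
    """Collapse an (n, L) nucleotide-code matrix into (n, L-nol+1) word codes
    in base 4 (leftmost letter most significant)."""
    if codes.ndim == 1:
        codes = codes[None, :]
    n, L = codes.shape
    if L < nol:
        raise ValueError(f"sequence length {L} shorter than word size {nol}")
    w = np.zeros((n, L - nol + 1), dtype=np.int64)
    for d in range(nol):
        w += codes[:, d : L - nol + 1 + d].astype(np.int64) * 4 ** (nol - 1 - d)
    return w


def _as_codes(column: Iterable[str] | np.ndarray) -> np.ndarray:
    if isinstance(column, np.ndarray) and column.dtype != object and column.dtype.kind in "iu":
        return column.astype(np.int64)
    joined = "".join(column)
    return encode(joined).astype(np.int64)


# ---------------------------------------------------------------------------
# vertical spectra


def column_entropy(
    column: Iterable[str] | np.ndarray, cfg: SpectrumConfig = SpectrumConfig()
) -> tuple[float, float]:
    """Shannon entropy of one alignment column (a residue multiset).

    Returns ``(value, se)`` in ``cfg.unit``. With ``bias_correction`` the
    Roulston first-order term (M̂−1)/(2N) nat is added.
    """
    codes = _as_codes(column)
    if codes.size == 0:
        raise ValueError("empty column")
    counts = np.bincount(codes, minlength=4 ** cfg.nol)
    h, se = _entropy_nat(counts, cfg.bias_correction)
    f = cfg.unit_factor
    return h * f, se * f


def vertical_entropy_spectrum(
    a: AlignmentSet, cfg: SpectrumConfig = SpectrumConfig()
) -> Spectrum:
    """Per-position VH spectrum: one bin per NOL-word start position."""
    codes = a.to_codes()
    if a.L < cfg.nol:
        raise ValueError(f"alignment length {a.L} < word size {cfg.nol}")
    words = _word_codes(codes, cfg.nol)
    P = words.shape[1]
    K = 4 ** cfg.nol
    counts = np.zeros((P, K), dtype=np.int64)
    np.add.at(counts, (np.broadcast_to(np.arange(P), words.shape), words), 1)
    vals = np.empty(P)
    ses = np.empty(P)
    for p in range(P):
        vals[p], ses[p] = _entropy_nat(counts[p], cfg.bias_correction)
    f = cfg.unit_factor
    return Spectrum(
        kind="VH",
        index=np.arange(1, P + 1),
        values=vals * f,
        se=ses * f,
        unit=cfg.unit,
        species=a.species,
        meta={"nol": cfg.nol, "bias_correction": cfg.bias_correction, "n": a.n},
    )


def joint_distribution_vertical(
    a: AlignmentSet, i: int, j: int, nol: int = 1
) -> JointDistribution:
    """Joint word-pair counts between columns ``i`` and ``j`` (0-based).

    The two NOL-letter windows must not overlap (``j >= i + nol``) and
    must fit inside the alignment.
    """
    if i >= j:
        raise ValueError(f"require i < j, got i={i}, j={j}")
    if j < i + nol:
        raise ValueError(f"overlapping word windows: j={j} < i+nol={i + nol}")
    if i < 0 or j + nol > a.L:
        raise ValueError(f"positions ({i}, {j}) with nol={nol} out of range for L={a.L}")
    words = _word_codes(a.to_codes(), nol)
    K = 4**nol
    joint = np.bincount(words[:, i] * K + words[:, j], minlength=K * K).reshape(K, K)
    return JointDistribution(joint, nol=nol)


def mutual_information(
    jd: JointDistribution, cfg: SpectrumConfig = SpectrumConfig()
) -> tuple[float, float]:
    """Mutual information of a joint word-pair distribution.

    Returns ``(value, se)`` in ``cfg.unit``; zero-probability cells
    contribute nothing; with ``bias_correction`` the Roulston term
    (M̂_xy − M̂_x − M̂_y + 1)/(2N) nat is subtracted.
    """
    mi, se = _mi_nat(jd.counts, cfg.bias_correction)
    f = cfg.unit_factor
    return mi * f, se * f


def vmi_matrix(a: AlignmentSet, cfg: SpectrumConfig = SpectrumConfig()) -> MIMatrix:
    """VMI over all non-overlapping position pairs, with SE per cell.

    Pairs are enumerated row-major: i ascending, j from i+NOL to the last
    word position, matching the fixed flattening order used when spectra
    are normalised for divergence computations.
    """
    nol = cfg.nol
    if a.L < 2 * nol:
        raise ValueError(f"alignment length {a.L} too short for nol={nol} pairs")
    words = _word_codes(a.to_codes(), nol)
    n, P = words.shape
    K = 4**nol

    # per-position word counts and single-column entropy ingredients
    col_counts = np.zeros((P, K), dtype=np.int64)
    np.add.at(col_counts, (np.broadcast_to(np.arange(P), words.shape), words), 1)
    col_p = col_counts / n
    with np.errstate(divide="ignore"):
        col_logp = np.where(col_counts > 0, np.log(np.maximum(col_p, 1e-300)), 0.0)
    m_states = (col_counts > 0).sum(axis=1)

    ii, jj, vv, ee = [], [], [], []
    for i in range(P - nol):
        js = np.arange(i + nol, P)
        nj = len(js)
        combos = words[:, [i]] * K + words[:, js]
        joint = np.zeros((nj, K * K), dtype=np.int64)
        np.add.at(joint, (np.broadcast_to(np.arange(nj), combos.shape), combos), 1)
        p = (joint / n).reshape(nj, K, K)
        nz = joint.reshape(nj, K, K) > 0
        with np.errstate(divide="ignore"):
            lnp = np.where(nz, np.log(np.maximum(p, 1e-300)), 0.0)
        term = np.where(
            nz, lnp - col_logp[i][None, :, None] - col_logp[js][:, None, :], 0.0
        )
        mi = (p * term).sum(axis=(1, 2))
        var = np.maximum(0.0, (p * term**2).sum(axis=(1, 2)) - mi**2) / n
        se = np.sqrt(var)
        if cfg.bias_correction:
            m_xy = nz.sum(axis=(1, 2))
            mi = mi - (m_xy - m_states[i] - m_states[js] + 1) / (2.0 * n)
        ii.append(np.full(nj, i))
        jj.append(js)
        vv.append(mi)
        ee.append(se)
    f = cfg.unit_factor
    return MIMatrix(
        i=np.concatenate(ii),
        j=np.concatenate(jj),
        values=np.concatenate(vv) * f,
        se=np.concatenate(ee) * f,
        n_positions=P,
        nol=nol,
        unit=cfg.unit,
        species=a.species,
    )


# ---------------------------------------------------------------------------
# horizontal spectra


def _hmi_joint_counts(word_row: np.ndarray, k: int, nol: int) -> np.ndarray:
    P = len(word_row)  # = L - nol + 1 word start positions
    n_pairs = P - k
    if n_pairs < 1:
        raise ValueError(f"lag k={k} leaves no word pairs (L too short)")
    K = 4**nol
    left = word_row[:n_pairs]
    right = word_row[k : k + n_pairs]
    return np.bincount(left * K + right, minlength=K * K).reshape(K, K)


def hmi_single_sequence(
    s: SequenceRecord | str, k: int, cfg: SpectrumConfig = SpectrumConfig()
) -> float:
    """Auto-mutual information of one sequence at lag ``k``.

    A cursor slides with step 1 collecting the ordered pair of NOL-words
    at positions (t, t+k) for every t that keeps both windows inside the
    sequence; MI of the resulting pair distribution is returned in
    ``cfg.unit``. Requires ``k >= 3`` and ``k >= nol`` (non-overlap).
    """
    if k < 3:
        raise ValueError(f"lag k must be >= 3, got {k}")
    if k < cfg.nol:
        raise ValueError(f"lag k={k} overlaps word windows of size {cfg.nol}")
    residues = s.residues if isinstance(s, SequenceRecord) else s
    words = _word_codes(encode(residues), cfg.nol)[0]
    joint = _hmi_joint_counts(words, k, cfg.nol)
    mi, _ = _mi_nat(joint, cfg.bias_correction)
    return mi * cfg.unit_factor


def hmi_spectrum(a: AlignmentSet, cfg: SpectrumConfig = SpectrumConfig()) -> Spectrum:
    """Ensemble HMI spectrum over lags k = 3 … ⌊L/2⌋.

    The per-bin value is the mean of the per-sequence HMI(k) across the
    species' n sequences; the per-bin SE is the ensemble standard error
    sd/√n (zero when n = 1). Bias correction, when enabled, is applied to
    each per-sequence estimate before averaging.
    """
    if a.L < 6:
        raise ValueError(f"alignment length {a.L} < 6; no lags in [3, L/2]")
    ks = np.arange(3, a.L // 2 + 1)
    codes = a.to_codes()
    words = _word_codes(codes, cfg.nol)
    vals = np.empty((a.n, len(ks)))
    for r in range(a.n):
        for c, k in enumerate(ks):
            joint = _hmi_joint_counts(words[r], int(k), cfg.nol)
            vals[r, c] = _mi_nat(joint, cfg.bias_correction)[0]
    mean = vals.mean(axis=0)
    if a.n > 1:
        se = vals.std(axis=0, ddof=1) / math.sqrt(a.n)
    else:
        se = np.zeros(len(ks))
    f = cfg.unit_factor
    return Spectrum(
        kind="HMI",
        index=ks,
        values=mean * f,
        se=se * f,
        unit=cfg.unit,
        species=a.species,
        meta={"nol": cfg.nol, "bias_correction": cfg.bias_correction, "n": a.n},
    )
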