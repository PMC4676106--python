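"""Informational distances between species spectra.

A spectrum is normalised into a probability vector over its bins
(negative bias-corrected bins clamped to zero), and two species are
compared by the Jensen–Shannon divergence

    JSD(P‖Q) = H((P+Q)/2) − (H(P) + H(Q)) / 2

with natural logarithms, so 0 ≤ JSD ≤ ln 2. The square root of JSD is a
metric and is the "informational distance" collected into species ×
species distance matrices. Because JSD is nonlinear, its standard error
is obtained by empirical (Monte-Carlo) propagation of the per-bin SEs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon_entropy, f_oneway

from .spectra import MIMatrix, Spectrum

__all__ = [
    "LN2",
    "NormalizedSpectrum",
    "DistanceMatrix",
    "DiscriminationReport",
    "normalize_spectrum",
    "jsd",
    "jsd_distance",
    "propagate_se",
    "distance_matrix",
    "discriminability_screen",
    "discrimination_calls",
]

LN2 = math.log(2.0)


@dataclass
class NormalizedSpectrum:
    """A spectrum reduced to a probability vector over its bins."""

    weights: np.ndarray
    kind: str
    index: np.ndarray
    source: str | None = None


@dataclass
class DistanceMatrix:
    """Symmetric √JSD distances between species with propagated SEs."""

    labels: list[str]
    d: np.ndarray
    se: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        k = len(self.labels)
        if self.d.shape != (k, k) or self.se.shape != (k, k):
            raise ValueError("distance/SE matrices must be square over labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.labels)):
            for j in range(i + 1, len(self.labels)):
                rows.append(
                    {
                        "a": self.labels[i],
                        "b": self.labels[j],
                        "distance": self.d[i, j],
                        "se": self.se[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _raw_values(s) -> tuple[np.ndarray, str, np.ndarray]:
    if isinstance(s, Spectrum):
        return np.asarray(s.values, dtype=float), s.kind, np.asarray(s.index)
    if isinstance(s, MIMatrix):
        return np.asarray(s.values, dtype=float), "VMI", np.arange(len(s))
    arr = np.asarray(s, dtype=float)
    return arr, "raw", np.arange(len(arr))


def normalize_spectrum(s) -> NormalizedSpectrum:
    """Clamp negative bins to 0 and normalise to unit sum.

    Accepts a :class:`Spectrum`, an :class:`MIMatrix` (flattened in its
    fixed row-major pair order) or a plain array. An all-zero spectrum is
    degenerate and an error.
    """
    vals, kind, index = _raw_values(s)
    w = np.clip(vals, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate spectrum: no positive bins to normalize")
    src = getattr(s, "species", None)
    return NormalizedSpectrum(weights=w / total, kind=kind, index=index, source=src)


def _check_compatible(p: NormalizedSpectrum, q: NormalizedSpectrum) -> None:
    if p.kind != q.kind:
        raise ValueError(f"spectrum kinds differ: {p.kind!r} vs {q.kind!r}")
    if len(p.weights) != len(q.weights):
        raise ValueError(
            f"bin counts differ: {len(p.weights)} vs {len(q.weights)}"
        )
    if len(p.index) == len(q.index) and not np.array_equal(p.index, q.index):
        raise ValueError("spectrum bin indices do not match")


def jsd(p: NormalizedSpectrum, q: NormalizedSpectrum) -> float:
    """Jensen–Shannon divergence (natural log) between matching spectra."""
    _check_compatible(p, q)
    a, b = p.weights, q.weights
    m = 0.5 * (a + b)
    val = _shannon_entropy(m) - 0.5 * (_shannon_entropy(a) + _shannon_entropy(b))
    return float(min(max(val, 0.0), LN2))


def jsd_distance(p: NormalizedSpectrum, q: NormalizedSpectrum) -> float:
    """√JSD — the informational distance (a metric)."""
    return math.sqrt(jsd(p, q))


def _jsd_rows(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Row-wise JSD for matched stacks of probability vectors."""

    def h(x: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(x > 0, x * np.log(x), 0.0)
        return -t.sum(axis=1)

    m = 0.5 * (P + Q)
    return np.clip(h(m) - 0.5 * (h(P) + h(Q)), 0.0, LN2)


def _perturbed_weights(values, se, rng, replicates) -> np.ndarray:
    draws = values[None, :] + rng.normal(size=(replicates, len(values))) * se[None, :]
    draws = np.clip(draws, 0.0, None)
    totals = draws.sum(axis=1, keepdims=True)
    base = np.clip(values, 0.0, None)
    base = base / base.sum()
    bad = totals[:, 0] <= 0
    if bad.any():
        draws[bad] = base
        totals = draws.sum(axis=1, keepdims=True)
    return draws / totals


def propagate_se(p, q, replicates: int = 200, seed: int = 0) -> float:
    """Monte-Carlo SE of √JSD from the per-bin SEs of two spectra.

    Each replicate perturbs every bin value with independent zero-mean
    Gaussian noise of that bin's SE, clamps at 0, renormalises and
    recomputes √JSD; the returned SE is the sd over replicates.
    Deterministic under ``seed``. Bins with value 0 and se 0 stay 0.
    """
    if replicates < 2:
        raise ValueError("propagation needs replicates >= 2")
    pv, pk, pi = _raw_values(p)
    qv, qk, qi = _raw_values(q)
    pse = np.asarray(getattr(p, "se"), dtype=float)
    qse = np.asarray(getattr(q, "se"), dtype=float)
    _check_compatible(
        NormalizedSpectrum(pv, pk, pi), NormalizedSpectrum(qv, qk, qi)
    )
    if not (pse.any() or qse.any()):
        return 0.0  # nothing to perturb
    # bins at exactly 0 with se 0 in both spectra stay 0 under perturbation
    # and contribute nothing to any entropy; dropping them is exact and
    # makes wide, mostly-conserved VMI spectra cheap to propagate
    active = (pv != 0) | (qv != 0) | (pse > 0) | (qse > 0)
    pv, qv, pse, qse = pv[active], qv[active], pse[active], qse[active]
    rng = np.random.default_rng(seed)
    dists = np.empty(replicates)
    # replicate chunks bound peak memory for very wide spectra (VMI)
    chunk = max(1, int(2_000_000 // max(len(pv), 1)))
    done = 0
    while done < replicates:
        c = min(chunk, replicates - done)
        P = _perturbed_weights(pv, pse, rng, c)
        Q = _perturbed_weights(qv, qse, rng, c)
        dists[done : done + c] = np.sqrt(_jsd_rows(P, Q))
        done += c
    return float(dists.std(ddof=1))


def _conform(spectra: dict[str, Spectrum | MIMatrix]):
    """Bring spectra onto a shared bin support.

    HMI spectra of differing lengths are truncated to the common k-range;
    VH and VMI spectra must already agree in bin structure.
    """
    items = list(spectra.items())
    kinds = {(_raw_values(s)[1]) for _, s in items}
    if len(kinds) != 1:
        raise ValueError(f"mixed spectrum kinds: {sorted(kinds)}")
    kind = kinds.pop()
    if kind == "HMI":
        lo = max(int(np.min(_raw_values(s)[2])) for _, s in items)
        hi = min(int(np.max(_raw_values(s)[2])) for _, s in items)
        if hi < lo:
            raise ValueError("HMI spectra share no common lag range")
        out = []
        for label, s in items:
            mask = (s.index >= lo) & (s.index <= hi)
            out.append(
                (
                    label,
                    Spectrum(
                        kind="HMI",
                        index=s.index[mask],
                        values=s.values[mask],
                        se=s.se[mask],
                        unit=s.unit,
                        species=s.species,
                        meta=dict(s.meta),
                    ),
                )
            )
        return out
    lengths = {len(_raw_values(s)[0]) for _, s in items}
    if len(lengths) != 1:
        raise ValueError(f"{kind} spectra have mismatched bin counts {sorted(lengths)}")
    return items


def distance_matrix(
    spectra: dict[str, Spectrum | MIMatrix],
    propagate: bool = True,
    replicates: int = 200,
    seed: int = 0,
    kind: str | None = None,
) -> DistanceMatrix:
    """All pairwise √JSD distances between species spectra, with SEs.

    Each unordered pair gets its own derived propagation seed so the
    matrix is independent of iteration order and reproducible.
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 species")
    items = _conform(spectra)
    labels = [lab for lab, _ in items]
    normed = [normalize_spectrum(s) for _, s in items]
    k = len(items)
    d = np.zeros((k, k))
    se = np.zeros((k, k))
    pair_no = 0
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = jsd_distance(normed[i], normed[j])
            if propagate:
                se[i, j] = se[j, i] = propagate_se(
                    items[i][1], items[j][1], replicates=replicates,
                    seed=(seed * 10007 + pair_no) % (2**31 - 1),
                )
            pair_no += 1
    return DistanceMatrix(labels=labels, d=d, se=se, kind=kind or normed[0].kind)


def discriminability_screen(spectra: list[Spectrum | MIMatrix]) -> float:
    """One-way ANOVA across spectra (each spectrum's bins form a group).

    A near-zero p-value says at least one spectrum differs from the
    others — the gating check before distance computation is worthwhile.
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra")
    groups = [_raw_values(s)[0] for s in spectra]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each spectrum needs at least 2 bins")
    if all(np.allclose(g, g[0]) for g in groups):
        raise ValueError("zero within-group variance in all groups; ANOVA undefined")
    return float(f_oneway(*groups).pvalue)


@dataclass
class DiscriminationReport:
    """Per-pair discrimination calls plus the stricter matrix-level summary."""

    calls: pd.DataFrame
    fraction_isolated: float


def discrimination_calls(dm: DistanceMatrix) -> DiscriminationReport:
    """Apply the CI rule d ± 2·SE to every species pair.

    The primary per-pair call is "discriminated" when the CI excludes 0.
    The matrix-level summary additionally reports the fraction of pairs
    whose CI overlaps no other pair's CI (mutual separation).
    """
    long = dm.to_long()
    long["ci_lo"] = long["distance"] - 2.0 * long["se"]
    long["ci_hi"] = long["distance"] + 2.0 * long["se"]
    long["discriminated"] = long["ci_lo"] > 0.0
    lo = long["ci_lo"].to_numpy()
    hi = long["ci_hi"].to_numpy()
    npairs = len(long)
    isolated = np.ones(npairs, dtype=bool)
    for i in range(npairs):
        for j in range(npairs):
            if i != j and hi[i] >= lo[j] and hi[j] >= lo[i]:
                isolated[i] = False
                break
    frac = float(isolated.mean()) if npairs else 0.0
    return DiscriminationReport(calls=long, fraction_isolated=frac)
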