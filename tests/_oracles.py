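"""Independent brute-force reference implementations.

Everything here uses nested Python loops, dictionaries and math.log only
— no numpy vectorisation and no code shared with the package — so these
serve as independent oracles for the estimators.
"""

import math
from collections import Counter

LN4 = math.log(4.0)


def entropy_nat(tokens, bias=False):
    """Plug-in Shannon entropy (nat) of a token multiset, optional
    first-order bias correction +(M-1)/(2N)."""
    counts = Counter(tokens)
    n = sum(counts.values())
    h = 0.0
    for c in counts.values():
        if c > 0:
            p = c / n
            h -= p * math.log(p)
    if bias:
        m = sum(1 for c in counts.values() if c > 0)
        h += (m - 1) / (2.0 * n)
    return h


def entropy_se_nat(tokens):
    counts = Counter(tokens)
    n = sum(counts.values())
    h = entropy_nat(tokens)
    s = 0.0
    for c in counts.values():
        p = c / n
        s += p * math.log(p) ** 2
    return math.sqrt(max(0.0, (s - h * h) / n))


def mi_nat(pairs, bias=False):
    """Plug-in MI (nat) of a list of ordered token pairs, optional bias
    correction -(Mxy - Mx - My + 1)/(2N)."""
    joint = Counter(pairs)
    left = Counter(a for a, _ in pairs)
    right = Counter(b for _, b in pairs)
    n = len(pairs)
    mi = 0.0
    for (a, b), c in joint.items():
        p = c / n
        mi += p * math.log(p * n * n / (left[a] * right[b]))
    if bias:
        mi -= (len(joint) - len(left) - len(right) + 1) / (2.0 * n)
    return mi


def mi_se_nat(pairs):
    joint = Counter(pairs)
    left = Counter(a for a, _ in pairs)
    right = Counter(b for _, b in pairs)
    n = len(pairs)
    mi = mi_nat(pairs)
    s = 0.0
    for (a, b), c in joint.items():
        p = c / n
        t = math.log(p * n * n / (left[a] * right[b]))
        s += p * t * t
    return math.sqrt(max(0.0, (s - mi * mi) / n))


def mi_via_entropies(pairs):
    """MI = H(X) + H(Y) - H(X,Y): the alternative identity route."""
    return (
        entropy_nat([a for a, _ in pairs])
        + entropy_nat([b for _, b in pairs])
        - entropy_nat(pairs)
    )


def words(seq, nol):
    return [seq[t : t + nol] for t in range(len(seq) - nol + 1)]


def vh_spectrum(rows, nol=1, bias=False):
    """Per word-start-position column entropies of aligned strings."""
    cols = []
    for p in range(len(rows[0]) - nol + 1):
        cols.append(entropy_nat([r[p : p + nol] for r in rows], bias=bias))
    return cols


def vmi(rows, nol=1, bias=False):
    """MI for every non-overlapping column pair, keyed by 0-based (i, j)."""
    out = {}
    P = len(rows[0]) - nol + 1
    for i in range(P):
        for j in range(i + nol, P):
            pairs = [(r[i : i + nol], r[j : j + nol]) for r in rows]
            out[(i, j)] = mi_nat(pairs, bias=bias)
    return out


def hmi(seq, k, nol=1, bias=False):
    """Auto-MI of one string at lag k over NOL-words."""
    w = words(seq, nol)
    pairs = [(w[t], w[t + k]) for t in range(len(w) - k)]
    return mi_nat(pairs, bias=bias)


def hmi_spectrum(rows, nol=1, bias=False):
    """Ensemble mean HMI(k) for k = 3 .. len//2."""
    L = len(rows[0])
    out = {}
    for k in range(3, L // 2 + 1):
        vals = [hmi(r, k, nol=nol, bias=bias) for r in rows]
        out[k] = sum(vals) / len(vals)
    return out


def jsd_nat(p, q):
    """Jensen-Shannon divergence with natural logs, element-wise loops."""

    def h(v):
        return -sum(x * math.log(x) for x in v if x > 0)

    m = [(a + b) / 2 for a, b in zip(p, q)]
    return h(m) - 0.5 * (h(p) + h(q))
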