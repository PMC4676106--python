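"""Informational dendrograms: WPGMA hierarchical clustering of √JSD
distance matrices and Newick export.

These are cluster diagrams of informational distances, explicitly not
phylogenetic trees. The WPGMA update gives the new cluster's distance to
any outsider as the plain mean of its two members' distances,
d(ab, x) = (d(a, x) + d(b, x)) / 2, and the merge height is half the
merged pair's distance (ultrametric convention), so leaf-to-root height
reads as half the cophenetic distance. Ties in the closest pair break
deterministically towards the lowest original label indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .divergence import DistanceMatrix

__all__ = ["DendroNode", "Dendrogram", "wpgma", "to_newick", "merge_table"]


@dataclass
class DendroNode:
    """A node of the dendrogram; ``height`` is 0 for leaves."""

    height: float
    label: str | None = None
    children: tuple["DendroNode", "DendroNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return self.children[0].leaves() + self.children[1].leaves()


@dataclass
class Dendrogram:
    root: DendroNode
    labels: list[str]
    #: scipy-style linkage rows [id_a, id_b, merge_distance, size]
    linkage: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))
    merges: list[tuple[int, str, str, float]] = field(default_factory=list)

    def leaf_sets(self) -> set[frozenset[str]]:
        """All clades as leaf-label sets (useful for cluster-membership checks)."""
        out: set[frozenset[str]] = set()

        def walk(node: DendroNode) -> None:
            out.add(frozenset(node.leaves()))
            if not node.is_leaf:
                walk(node.children[0])
                walk(node.children[1])

        walk(self.root)
        return out


def wpgma(dm: DistanceMatrix) -> Dendrogram:
    """Weighted pair-group clustering (WPGMA) of a distance matrix.

    Iteratively merges the closest pair of clusters; the merged node sits
    at height d/2 and its distance to every other cluster is the mean of
    the two members' distances.
    """
    d0 = np.asarray(dm.d, dtype=float)
    if np.isnan(d0).any():
        raise ValueError("distance matrix contains NaN")
    k = len(dm.labels)
    if k < 2:
        raise ValueError("need at least 2 labels to cluster")

    # active clusters: cluster-id -> (node, min original label index, scipy id)
    nodes: dict[int, DendroNode] = {
        i: DendroNode(height=0.0, label=dm.labels[i]) for i in range(k)
    }
    min_idx = {i: i for i in range(k)}
    scipy_id = {i: i for i in range(k)}
    sizes = {i: 1 for i in range(k)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(d0[i, j]) for i in range(k) for j in range(i + 1, k)
    }
    linkage_rows = []
    merges: list[tuple[int, str, str, float]] = []
    next_id = k
    next_scipy = k
    active = set(range(k))
    step = 0
    while len(active) > 1:
        # closest pair; tie-break on (min original index of a, of b)
        best = min(
            dist.items(),
            key=lambda kv: (
                kv[1],
                min(min_idx[kv[0][0]], min_idx[kv[0][1]]),
                max(min_idx[kv[0][0]], min_idx[kv[0][1]]),
            ),
        )
        (a, b), dab = best
        new = DendroNode(height=dab / 2.0, children=(nodes[a], nodes[b]))
        step += 1
        merges.append(
            (step, ",".join(nodes[a].leaves()), ",".join(nodes[b].leaves()), dab / 2.0)
        )
        linkage_rows.append([scipy_id[a], scipy_id[b], dab, sizes[a] + sizes[b]])
        active -= {a, b}
        for x in active:
            da = dist[(min(a, x), max(a, x))]
            db = dist[(min(b, x), max(b, x))]
            dist[(min(next_id, x), max(next_id, x))] = 0.5 * (da + db)
        dist = {
            pair: v for pair, v in dist.items() if a not in pair and b not in pair
        }
        nodes[next_id] = new
        min_idx[next_id] = min(min_idx[a], min_idx[b])
        scipy_id[next_id] = next_scipy
        sizes[next_id] = sizes[a] + sizes[b]
        active.add(next_id)
        next_id += 1
        next_scipy += 1
    root = nodes[next_id - 1]
    return Dendrogram(
        root=root,
        labels=list(dm.labels),
        linkage=np.asarray(linkage_rows, dtype=float),
        merges=merges,
    )


def _quote(label: str) -> str:
    if any(c in label for c in " \t()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_node(node: DendroNode, parent_height: float) -> str:
    bl = parent_height - node.height
    if node.is_leaf:
        return f"{_quote(node.label)}:{bl:.10g}"
    inner = ",".join(_newick_node(c, node.height) for c in node.children)
    return f"({inner}):{bl:.10g}"


def to_newick(t: Dendrogram) -> str:
    """Serialise with branch lengths; leaves sit at height 0, so branch
    length = parent height − child height."""
    root = t.root
    if root.is_leaf:
        return f"{_quote(root.label)}:0;"
    inner = ",".join(_newick_node(c, root.height) for c in root.children)
    return f"({inner});"


def merge_table(t: Dendrogram) -> pd.DataFrame:
    """Flat record of the merge sequence: step, members, merge height."""
    return pd.DataFrame(
        t.merges, columns=["step", "member_a", "member_b", "height"]
    )
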