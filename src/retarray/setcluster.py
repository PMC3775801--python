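"""Variation-of-information distances between gene sets and their clustering.

Each gene set S over a detected-gene universe U induces the binary partition
{S, U \\ S}.  The variation of information between two such partitions,

    VI = H(P_a) + H(P_b) - 2 I(P_a; P_b)        (entropies in bits),

is a true metric on partitions and serves as the distance for average-linkage
hierarchical clustering of the significant sets, so that heavily overlapping
gene-ontology-style terms are reported together rather than as independent
findings.  Note the one degeneracy of the binary-partition construction:
a set and its exact complement induce the same partition and are at distance
zero — unreachable in practice for small term-like sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list, to_tree
from scipy.spatial.distance import squareform

__all__ = ["vi_distance", "cluster_sets", "VIDistanceMatrix"]


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def vi_distance(a, b, universe) -> float:
    """VI in bits between the binary partitions induced by sets ``a`` and
    ``b`` over ``universe`` (cell probabilities = cell sizes / |universe|)."""
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = frozenset(a), frozenset(b)
    if not a <= universe or not b <= universe:
        raise ValueError("sets must be subsets of the universe")
    n = len(universe)
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = n - n11 - n10 - n01
    # sorted cells keep the summation order, hence the float result,
    # invariant under swapping a and b (symmetry must be exact)
    joint = np.sort(np.array([n11, n10, n01, n00], dtype=float)) / n
    pa = np.array([len(a), n - len(a)], dtype=float) / n
    pb = np.array([len(b), n - len(b)], dtype=float) / n
    h_joint = _entropy_bits(joint)
    h_ab = _entropy_bits(pa) + _entropy_bits(pb)
    # VI = H(a) + H(b) - 2 I(a;b) = 2 H(joint) - H(a) - H(b)
    return max(0.0, 2.0 * h_joint - h_ab)


@dataclass
class VIDistanceMatrix:
    """Pairwise VI distances plus the average-linkage tree over gene sets."""

    names: list
    matrix: np.ndarray           # symmetric, zero diagonal, bits
    linkage: np.ndarray | None   # scipy linkage table (None for < 2 sets)
    shared_members: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.names, columns=self.names)

    def leaf_order(self) -> list:
        if self.linkage is None:
            return list(self.names)
        return [self.names[i] for i in leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Dendrogram of set names, branch lengths from merge heights."""
        if self.linkage is None:
            return f"({self.names[0]});" if self.names else "();"
        root = to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.names[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({rec(root.left, root.dist)},{rec(root.right, root.dist)});"


def cluster_sets(sets: dict, universe) -> VIDistanceMatrix:
    """VI distance matrix + average-linkage clustering of named gene sets.

    ``sets`` maps name -> members.  The report also tabulates, for each
    merge of two original sets, their shared-member count (clustered sets
    generally share many members).
    """
    names = list(sets)
    k = len(names)
    if k == 0:
        raise ValueError("no sets to cluster")
    dist = np.zeros((k, k))
    shared_rows = []
    for i in range(k):
        for j in range(i + 1, k):
            d = vi_distance(sets[names[i]], sets[names[j]], universe)
            dist[i, j] = dist[j, i] = d
            shared_rows.append({
                "set_a": names[i], "set_b": names[j], "vi_bits": d,
                "shared": len(frozenset(sets[names[i]]) & frozenset(sets[names[j]])),
            })
    shared = pd.DataFrame(shared_rows).sort_values("vi_bits").reset_index(drop=True) \
        if shared_rows else None
    linkage = average(squareform(dist, checks=False)) if k >= 2 else None
    return VIDistanceMatrix(names=names, matrix=dist, linkage=linkage,
                            shared_members=shared)
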