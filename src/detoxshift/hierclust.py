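"""Agglomerative hierarchical clustering with a deterministic tie-break.

Complete linkage and UPGMA (unweighted average) are provided.  Ties in merge
height are broken by the lexicographically smallest (min label, max label)
pair, where a cluster is identified by the smallest leaf label it contains;
this makes the merge tree invariant to permutations of the input rows up to
relabelling, which scipy's condensed-index tie-break does not guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ValidationError

__all__ = ["ClusterNode", "Dendrogram", "hierarchical_cluster", "cut_into_k"]

LINKAGES = ("complete", "upgma")


@dataclass
class ClusterNode:
    """Node of a merge tree; leaves carry item labels, internal nodes heights."""

    height: float = 0.0
    label: str | None = None
    children: tuple["ClusterNode", ...] = ()
    merge_index: int = -1  # order in which the merge happened (leaves: -1)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Dendrogram:
    """Binary merge tree over n items with n-1 internal nodes."""

    root: ClusterNode
    items: list[str] = field(default_factory=list)

    def nodes(self) -> list[ClusterNode]:
        out: list[ClusterNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out

    def merge_heights(self) -> list[float]:
        """Heights of internal merges in merge order (non-decreasing)."""
        internals = [n for n in self.nodes() if not n.is_leaf]
        internals.sort(key=lambda n: n.merge_index)
        return [n.height for n in internals]

    def leaf_sets(self) -> set[frozenset[str]]:
        """Leaf set of every node (used for subtree-contiguity checks)."""
        return {frozenset(n.leaves()) for n in self.nodes()}

    def to_newick(self) -> str:
        """Newick with branch lengths derived from merge heights."""

        def fmt(node: ClusterNode, parent_height: float) -> str:
            if node.is_leaf:
                core = str(node.label)
                height = 0.0
            else:
                core = "(" + ",".join(fmt(c, node.height) for c in node.children) + ")"
                height = node.height
            return f"{core}:{parent_height - height:g}"

        if self.root.is_leaf:
            return f"{self.root.label};"
        inner = ",".join(fmt(c, self.root.height) for c in self.root.children)
        return f"({inner});"


def _pair_key(a: ClusterNode, b: ClusterNode, mins: dict[int, str]) -> tuple[str, str]:
    la, lb = mins[id(a)], mins[id(b)]
    return (min(la, lb), max(la, lb))


def hierarchical_cluster(
    dist: pd.DataFrame, linkage: str = "complete"
) -> Dendrogram:
    """Agglomerate items of a symmetric distance matrix into a Dendrogram.

    Parameters
    ----------
    dist
        Symmetric non-negative distance matrix with identical, unique row and
        column labels and zero diagonal.
    linkage
        ``"complete"`` (maximum) or ``"upgma"`` (unweighted average).
    """
    if linkage not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    labels = [str(x) for x in dist.index]
    if len(labels) < 2:
        raise ValidationError("need at least 2 items to cluster")
    if list(dist.columns.astype(str)) != labels:
        raise ValidationError("distance matrix rows/columns must match")
    d = dist.to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise ValidationError("distance matrix must be symmetric")

    clusters: dict[int, ClusterNode] = {}
    sizes: dict[int, int] = {}
    mins: dict[int, str] = {}  # smallest leaf label per live cluster
    # pairwise linkage distances between live clusters, keyed by id pairs
    live: list[ClusterNode] = []
    for lab in labels:
        node = ClusterNode(label=lab)
        clusters[id(node)] = node
        sizes[id(node)] = 1
        mins[id(node)] = lab
        live.append(node)
    dmat: dict[frozenset[int], float] = {}
    for i in range(len(live)):
        for j in range(i + 1, len(live)):
            dmat[frozenset((id(live[i]), id(live[j])))] = d[i, j]

    merge_index = 0
    while len(live) > 1:
        # pick min-distance pair; ties by lexicographic (min label, max label)
        best = None
        for i in range(len(live)):
            for j in range(i + 1, len(live)):
                a, b = live[i], live[j]
                dij = dmat[frozenset((id(a), id(b)))]
                key = (dij, *_pair_key(a, b, mins))
                if best is None or key < best[0]:
                    best = (key, a, b)
        assert best is not None
        (height, *_), a, b = best
        # order children so the cluster with the smaller min label is first
        first, second = (a, b) if mins[id(a)] <= mins[id(b)] else (b, a)
        merged = ClusterNode(
            height=height, children=(first, second), merge_index=merge_index
        )
        merge_index += 1
        na, nb = sizes[id(a)], sizes[id(b)]
        sizes[id(merged)] = na + nb
        mins[id(merged)] = min(mins[id(a)], mins[id(b)])
        for other in live:
            if other is a or other is b:
                continue
            da = dmat.pop(frozenset((id(a), id(other))))
            db = dmat.pop(frozenset((id(b), id(other))))
            if linkage == "complete":
                dnew = max(da, db)
            else:  # upgma: size-weighted (unweighted over original items)
                dnew = (na * da + nb * db) / (na + nb)
            dmat[frozenset((id(merged), id(other)))] = dnew
        dmat.pop(frozenset((id(a), id(b))))
        live = [c for c in live if c is not a and c is not b] + [merged]

    return Dendrogram(root=live[0], items=labels)


def cut_into_k(dendrogram: Dendrogram, k: int) -> list[frozenset[str]]:
    """Partition the items into k clusters by undoing the k-1 last merges.

    Merges happen in non-decreasing height order, so removing the last k-1
    merges removes the k-1 highest ones (with ties resolved by merge order).
    Clusters are returned sorted by their smallest member label.
    """
    n = len(dendrogram.items)
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    cutoff = (n - 1) - (k - 1)  # keep merges with merge_index < cutoff

    clusters: list[frozenset[str]] = []

    def collect(node: ClusterNode) -> None:
        if node.is_leaf or node.merge_index < cutoff:
            clusters.append(frozenset(node.leaves()))
        else:
            for c in node.children:
                collect(c)

    collect(dendrogram.root)
    return sorted(clusters, key=lambda s: min(s))
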