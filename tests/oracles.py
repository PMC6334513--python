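"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — direct enumeration, O(n^2) textbook
definitions, explicit double loops — and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from detoxshift.types import Phylogeny, TreeNode


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def random_binary_tree(n_tips: int, rng, blen=(0.05, 2.0)) -> Phylogeny:
    """Random topology by sequential joining; random branch lengths."""
    nodes = [
        TreeNode(label=f"t{i}", length=float(rng.uniform(*blen)))
        for i in range(n_tips)
    ]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(TreeNode(length=float(rng.uniform(*blen)), children=[a, b]))
    nodes[0].length = 0.0
    return Phylogeny(nodes[0])


def balanced_tree(depth: int, rng, blen=(0.1, 0.4)) -> Phylogeny:
    counter = [0]

    def build(d: int) -> TreeNode:
        if d == 0:
            counter[0] += 1
            return TreeNode(label=f"t{counter[0]}", length=float(rng.uniform(*blen)))
        return TreeNode(
            length=float(rng.uniform(*blen)), children=[build(d - 1), build(d - 1)]
        )

    root = build(depth)
    root.length = 0.0
    return Phylogeny(root)


def _parent_map(tree: Phylogeny) -> dict[int, TreeNode]:
    parent: dict[int, TreeNode] = {}
    for node in tree.postorder():
        for child in node.children:
            parent[id(child)] = node
    return parent


def _transition(rate: float, t: float) -> np.ndarray:
    change = (1.0 - math.exp(-2.0 * rate * t)) / 2.0
    return np.array([[1 - change, change], [change, 1 - change]])


def enum_loglik(tree: Phylogeny, tip_states: dict[str, int], rate: float) -> float:
    """Likelihood by explicit sum over all internal-state assignments."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    parent = _parent_map(tree)
    total = 0.0
    for assign in itertools.product((0, 1), repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        for t in tree.tips:
            amap[id(t)] = tip_states[t.label]
        prob = 0.5  # uniform root prior
        for node in tree.postorder():
            if node is tree.root:
                continue
            P = _transition(rate, node.length)
            prob *= P[amap[id(parent[id(node)])], amap[id(node)]]
        total += prob
    return math.log(total)


def enum_marginals(
    tree: Phylogeny, tip_states: dict[str, int], rate: float
) -> dict[int, np.ndarray]:
    """P(node = s | tips) by enumeration of P(node = s, tips) / P(tips)."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    parent = _parent_map(tree)
    joint = {id(n): np.zeros(2) for n in tree.postorder()}
    for assign in itertools.product((0, 1), repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        for t in tree.tips:
            amap[id(t)] = tip_states[t.label]
        prob = 0.5
        for node in tree.postorder():
            if node is tree.root:
                continue
            P = _transition(rate, node.length)
            prob *= P[amap[id(parent[id(node)])], amap[id(node)]]
        for node in tree.postorder():
            joint[id(node)][amap[id(node)]] += prob
    return {k: v / v.sum() for k, v in joint.items()}


def enum_mp(
    tree: Phylogeny, tip_states: dict[str, int]
) -> tuple[dict[int, frozenset[int]], int]:
    """MP state sets and minimum change count by labelling enumeration."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    parent = _parent_map(tree)
    scored = []
    for assign in itertools.product((0, 1), repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        for t in tree.tips:
            amap[id(t)] = tip_states[t.label]
        changes = sum(
            1
            for node in tree.postorder()
            if node is not tree.root and amap[id(parent[id(node)])] != amap[id(node)]
        )
        scored.append((changes, dict(amap)))
    best = min(c for c, _ in scored)
    sets: dict[int, set[int]] = {id(n): set() for n in tree.postorder()}
    for c, amap in scored:
        if c == best:
            for nid, s in amap.items():
                sets[nid].add(s)
    return {k: frozenset(v) for k, v in sets.items()}, best


def fitch_changes(tree: Phylogeny, tip_states: dict[str, int]) -> int:
    """Fitch up-pass change count (independent of the Sankoff route)."""
    count = 0

    def visit(node: TreeNode) -> set[int]:
        nonlocal count
        if node.is_leaf:
            return {tip_states[node.label]}
        child_sets = [visit(c) for c in node.children]
        inter = set.intersection(*child_sets)
        if inter:
            return inter
        # binary state space: each child set missing from the running
        # intersection costs one change under Fitch's rule
        current = child_sets[0]
        for cs in child_sets[1:]:
            if current & cs:
                current = current & cs
            else:
                current = current | cs
                count += 1
        return current

    visit(tree.root)
    return count


# ---------------------------------------------------------------------------
# Simple numeric oracles
# ---------------------------------------------------------------------------


def bh_stepup(pvalues: np.ndarray) -> np.ndarray:
    """Textbook O(n^2) Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(n)
    for rank_pos in range(n):
        idx = order[rank_pos]
        rank = rank_pos + 1
        candidates = []
        for later_pos in range(rank_pos, n):
            jdx = order[later_pos]
            candidates.append(p[jdx] * n / (later_pos + 1))
        adjusted[idx] = min(1.0, min(candidates))
    return adjusted


def pairwise_binary_euclidean(arr: np.ndarray) -> np.ndarray:
    """Double-loop Euclidean distance between binary rows."""
    n = arr.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = math.sqrt(sum((arr[i, k] - arr[j, k]) ** 2 for k in range(arr.shape[1])))
    return out
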