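"""Ancestral reconstruction of binary host-range characters.

Two reconstructions are provided for each host taxon, treated as an
independent binary (absent/present) character at the tree tips:

* **Maximum likelihood** under the symmetric two-state Markov (Mk, equal
  rates) model.  Over a branch of length ``t`` at rate ``q`` the transition
  probabilities are ``P(stay) = (1 + exp(-2 q t)) / 2`` and ``P(change) =
  (1 - exp(-2 q t)) / 2``; the root is weighted by the model's stationary
  prior (1/2, 1/2).  The single free rate is fitted by bounded 1-D
  optimization of the pruning (post-order partial likelihood) log-likelihood,
  and marginal node probabilities are obtained from combined upward partials
  and a downward pass, i.e. each node's posterior given *all* tips.
* **Maximum parsimony** state sets via the Sankoff dynamic programme with
  unit change cost: a node's MP set contains every state attainable in at
  least one minimum-change labelling.

Multifurcating nodes are handled natively (products over all children);
zero-length branches use exact identity transition matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .types import HostRangeMatrix, Phylogeny, TreeNode, ValidationError

__all__ = [
    "mk_transition_matrix",
    "mk_likelihood",
    "estimate_rate_ml",
    "marginal_ancestral",
    "mp_reconstruct",
    "AncestralEstimate",
    "ancestral_host_report",
    "node_names",
]

STATES = ("absent", "present")
ROOT_PRIOR = np.array([0.5, 0.5])
RATE_BOUNDS = (1e-9, 100.0)
RATE_XTOL = 1e-8


def mk_transition_matrix(rate: float, t: float) -> np.ndarray:
    """2x2 transition matrix of the symmetric 2-state Markov model."""
    if rate < 0:
        raise ValidationError(f"rate must be non-negative, got {rate}")
    if t < 0:
        raise ValidationError(f"branch length must be non-negative, got {t}")
    change = (1.0 - math.exp(-2.0 * rate * t)) / 2.0
    stay = 1.0 - change
    return np.array([[stay, change], [change, stay]])


def _check_tip_states(tree: Phylogeny, tip_states: dict[str, int]) -> None:
    missing = [lab for lab in tree.tip_labels if lab not in tip_states]
    if missing:
        raise ValidationError(f"tip(s) missing a state: {missing}")
    bad = {k: v for k, v in tip_states.items() if v not in (0, 1)}
    if bad:
        k, v = next(iter(bad.items()))
        raise ValidationError(f"tip state must be 0/1, got {v!r} for {k!r}")


def _upward_partials(
    tree: Phylogeny, tip_states: dict[str, int], rate: float
) -> tuple[dict[int, np.ndarray], float]:
    """Post-order (pruning) partial likelihoods, rescaled per node.

    Returns a map id(node) -> normalized partial vector and the accumulated
    log of the scaling factors.
    """
    partials: dict[int, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder():
        if node.is_leaf:
            vec = np.zeros(2)
            vec[tip_states[node.label]] = 1.0  # type: ignore[index]
        else:
            vec = np.ones(2)
            for child in node.children:
                pmat = mk_transition_matrix(rate, child.length)
                vec = vec * (pmat @ partials[id(child)])
        total = vec.sum()
        if total <= 0:
            raise ValidationError("zero likelihood encountered in pruning")
        partials[id(node)] = vec / total
        log_scale += math.log(total)
    return partials, log_scale


def mk_likelihood(
    tree: Phylogeny, tip_states: dict[str, int], rate: float
) -> float:
    """Log-likelihood of one binary character under the equal-rates model."""
    _check_tip_states(tree, tip_states)
    partials, log_scale = _upward_partials(tree, tip_states, rate)
    root_like = float(ROOT_PRIOR @ partials[id(tree.root)])
    return math.log(root_like) + log_scale


def estimate_rate_ml(
    tree: Phylogeny, characters: dict[str, int] | list[dict[str, int]]
) -> float:
    """MLE of the single Mk rate, pooled over one or more characters.

    Constant characters (all tips sharing a state) push the likelihood to be
    monotone decreasing in the rate, so the boundary value 0 is returned when
    every supplied character is constant.
    """
    chars = [characters] if isinstance(characters, dict) else list(characters)
    if not chars:
        raise ValidationError("no characters supplied")
    for c in chars:
        _check_tip_states(tree, c)
    labels = tree.tip_labels
    if all(len({c[lab] for lab in labels}) == 1 for c in chars):
        return 0.0

    def neg_loglik(rate: float) -> float:
        return -sum(mk_likelihood(tree, c, rate) for c in chars)

    res = minimize_scalar(
        neg_loglik,
        bounds=RATE_BOUNDS,
        method="bounded",
        options={"xatol": RATE_XTOL},
    )
    if not res.success:
        raise RuntimeError(f"rate optimization failed: {res.message}")
    rate = float(res.x)
    # prefer the exact boundary when the optimum sits against it
    if neg_loglik(RATE_BOUNDS[0]) <= res.fun:
        return RATE_BOUNDS[0]
    return rate


def marginal_ancestral(
    tree: Phylogeny, tip_states: dict[str, int], rate: float
) -> dict[int, np.ndarray]:
    """Marginal posterior state probabilities for every node.

    Combines the upward (pruning) partials with a pre-order downward pass so
    that each node's vector conditions on all tips; keyed by ``id(node)``.
    Tips get degenerate vectors; every vector sums to 1.
    """
    _check_tip_states(tree, tip_states)
    partials, _ = _upward_partials(tree, tip_states, rate)

    outside: dict[int, np.ndarray] = {id(tree.root): ROOT_PRIOR.copy()}
    marginals: dict[int, np.ndarray] = {}
    for node in tree.preorder():
        out = outside[id(node)]
        post = out * partials[id(node)]
        marginals[id(node)] = post / post.sum()
        if node.is_leaf:
            continue
        # message each child: parent-side outside x siblings' upward messages
        child_msgs = []
        for child in node.children:
            pmat = mk_transition_matrix(rate, child.length)
            child_msgs.append(pmat @ partials[id(child)])
        for i, child in enumerate(node.children):
            parent_term = out.copy()
            for j, msg in enumerate(child_msgs):
                if j != i:
                    parent_term = parent_term * msg
            pmat = mk_transition_matrix(rate, child.length)
            vec = pmat.T @ parent_term
            outside[id(child)] = vec / vec.sum()
    return marginals


def mp_reconstruct(
    tree: Phylogeny, tip_states: dict[str, int]
) -> tuple[dict[int, frozenset[int]], int]:
    """Most-parsimonious state sets (Sankoff, unit costs) per node.

    Returns a map id(node) -> set of states attainable in at least one
    minimum-change labelling, and the minimum change count.
    """
    _check_tip_states(tree, tip_states)
    big = 10**9
    up: dict[int, np.ndarray] = {}  # min changes within subtree given node state
    for node in tree.postorder():
        if node.is_leaf:
            cost = np.array([0 if tip_states[node.label] == s else big for s in (0, 1)])
        else:
            cost = np.zeros(2, dtype=np.int64)
            for child in node.children:
                ccost = up[id(child)]
                # unit substitution cost on the child branch
                cost += np.array(
                    [min(ccost[0], ccost[1] + 1), min(ccost[0] + 1, ccost[1])]
                )
        up[id(node)] = cost

    min_changes = int(up[id(tree.root)].min())
    down: dict[int, np.ndarray] = {id(tree.root): np.zeros(2, dtype=np.int64)}
    sets: dict[int, frozenset[int]] = {}
    for node in tree.preorder():
        total = up[id(node)] + down[id(node)]
        best = total.min()
        sets[id(node)] = frozenset(int(s) for s in (0, 1) if total[s] == best)
        if node.is_leaf:
            continue
        child_msg = {}
        for child in node.children:
            ccost = up[id(child)]
            child_msg[id(child)] = np.array(
                [min(ccost[0], ccost[1] + 1), min(ccost[0] + 1, ccost[1])]
            )
        for child in node.children:
            # cost of the rest of the tree given the child's state
            rest = np.zeros(2, dtype=np.int64)
            for t in (0, 1):
                parent_cost = down[id(node)][t] + sum(
                    child_msg[id(c)][t] for c in node.children if c is not child
                )
                rest[t] = parent_cost
            ccost = up[id(child)]
            down[id(child)] = np.array(
                [
                    min(rest[0], rest[1] + 1),
                    min(rest[0] + 1, rest[1]),
                ]
            )
    return sets, min_changes


def node_names(tree: Phylogeny) -> dict[int, str]:
    """Stable display names: tip labels, or ``node<k>`` in post-order."""
    names: dict[int, str] = {}
    k = 0
    for node in tree.postorder():
        if node.is_leaf:
            names[id(node)] = str(node.label)
        else:
            names[id(node)] = node.label or f"node{k}"
            k += 1
    return names


@dataclass(frozen=True)
class AncestralEstimate:
    """Per-character reconstruction summary plus per-node detail."""

    character: str
    rate: float
    root_p_present: float
    mp_root_set: frozenset[int]
    min_changes: int
    node_marginals: pd.DataFrame  # index: node name, columns: absent/present
    node_mp_sets: dict[str, frozenset[int]]


def ancestral_host_report(
    tree: Phylogeny, host_matrix: HostRangeMatrix
) -> list[AncestralEstimate]:
    """Reconstruct every host-taxon character on the tree.

    Tips must all be rows of the host matrix.  Results are sorted by the
    root's present-probability, descending.
    """
    missing = [t for t in tree.tip_labels if t not in host_matrix.groups]
    if missing:
        raise ValidationError(f"tree tip(s) absent from host matrix: {missing}")
    names = node_names(tree)
    estimates = []
    for taxon in host_matrix.taxa:
        tip_states = {t: host_matrix.character(taxon)[t] for t in tree.tip_labels}
        rate = estimate_rate_ml(tree, tip_states)
        marg = marginal_ancestral(tree, tip_states, rate)
        sets, changes = mp_reconstruct(tree, tip_states)
        rows = {names[nid]: vec for nid, vec in marg.items()}
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(STATES))
        root_p = float(marg[id(tree.root)][1])
        estimates.append(
            AncestralEstimate(
                character=taxon,
                rate=rate,
                root_p_present=root_p,
                mp_root_set=sets[id(tree.root)],
                min_changes=changes,
                node_marginals=df,
                node_mp_sets={names[nid]: s for nid, s in sets.items()},
            )
        )
    estimates.sort(key=lambda e: -e.root_p_present)
    return estimates


def report_table(estimates: list[AncestralEstimate]) -> pd.DataFrame:
    """Tabular summary of :func:`ancestral_host_report` output."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "character": e.character,
                "rate": e.rate,
                "root_p_present": e.root_p_present,
                "mp_root_set": "/".join(STATES[s] for s in sorted(e.mp_root_set)),
                "min_changes": e.min_changes,
            }
        )
    return pd.DataFrame(rows)
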