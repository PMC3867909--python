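"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's pruning recursion and
summarisation code paths: likelihoods come from exhaustive enumeration over
interior-node state assignments, transition matrices from generic matrix
exponentiation, and tree topologies from direct recursive construction.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm

from bathyphy import CharacterData, MkModel
from bathyphy.trees import PhyloTree, parse_newick


def expm_transition_matrix(k: int, alpha: float, t: float) -> np.ndarray:
    """Equal-rates Mk transition matrix via generic matrix exponentiation."""
    q = np.full((k, k), alpha)
    np.fill_diagonal(q, -(k - 1) * alpha)
    return expm(q * t)


def enumerate_rooted_topologies(labels: tuple[str, ...]) -> list:
    """All rooted binary tree topologies on the given leaf labels.

    Trees are nested 2-tuples of labels; there are (2n-3)!! of them.
    """
    if len(labels) == 1:
        return [labels[0]]
    if len(labels) == 2:
        return [(labels[0], labels[1])]
    head, rest = labels[-1], labels[:-1]
    out = []
    for tree in enumerate_rooted_topologies(rest):
        out.extend(_insert_on_every_edge(tree, head))
    return out


def _insert_on_every_edge(tree, leaf):
    results = [(tree, leaf)]  # insert above the current root
    if isinstance(tree, tuple):
        left, right = tree
        results.extend((new_left, right) for new_left in _insert_on_every_edge(left, leaf))
        results.extend((left, new_right) for new_right in _insert_on_every_edge(right, leaf))
    return results


def topology_to_newick(tree, branch_lengths: dict | None = None) -> str:
    """Nested-tuple topology -> Newick; `branch_lengths` keys are leaf-label
    frozensets of each clade/leaf."""

    def render(node):
        if isinstance(node, str):
            key = frozenset({node})
            label = node
        else:
            key = frozenset(topology_leaves(node))
            label = f"({render(node[0])},{render(node[1])})"
        if branch_lengths is not None and key in branch_lengths:
            label += f":{branch_lengths[key]!r}"
        return label

    return render(tree) + ";"


def topology_leaves(tree) -> list[str]:
    if isinstance(tree, str):
        return [tree]
    return topology_leaves(tree[0]) + topology_leaves(tree[1])


def topology_clade_keys(tree) -> list[frozenset]:
    """Keys (leaf-label frozensets) of every node except the root, root last excluded."""
    keys = []

    def walk(node, is_root):
        if isinstance(node, str):
            if not is_root:
                keys.append(frozenset({node}))
            return
        if not is_root:
            keys.append(frozenset(topology_leaves(node)))
        walk(node[0], False)
        walk(node[1], False)

    walk(tree, True)
    return keys


def build_tree(tree, branch_lengths: dict) -> PhyloTree:
    return parse_newick(topology_to_newick(tree, branch_lengths), rooted=True)


def brute_force_likelihoods(
    tree, branch_lengths: dict, chars: CharacterData, model: MkModel
) -> tuple[float, dict[frozenset, np.ndarray]]:
    """(log-likelihood, marginals) by exhaustive enumeration.

    Sums the joint probability of tip data over every assignment of states
    to interior nodes, under a uniform root prior; marginals are the
    per-node sums grouped by that node's state.
    """
    k = model.k

    internal: list[frozenset] = []

    def collect(node):
        if isinstance(node, tuple):
            internal.append(frozenset(topology_leaves(node)))
            collect(node[0])
            collect(node[1])

    collect(tree)
    m = len(internal)
    index = {key: i for i, key in enumerate(internal)}

    pmats = {
        key: expm_transition_matrix(k, model.alpha, t)
        for key, t in branch_lengths.items()
    }

    def edges(node):
        out = []
        if isinstance(node, tuple):
            parent_key = frozenset(topology_leaves(node))
            for child in node:
                child_key = (
                    frozenset({child}) if isinstance(child, str)
                    else frozenset(topology_leaves(child))
                )
                out.append((parent_key, child, child_key))
                out.extend(edges(child))
        return out

    edge_list = edges(tree)
    total = 0.0
    marg = {key: np.zeros(k) for key in internal}
    for assignment in itertools.product(range(k), repeat=m):
        prob = 1.0 / k  # uniform root prior
        for parent_key, child, child_key in edge_list:
            sp = assignment[index[parent_key]]
            if isinstance(child, str):
                sc = chars.state_of(child)
                if sc is None:
                    continue  # missing tip: marginalised out, contributes 1
            else:
                sc = assignment[index[child_key]]
            prob *= pmats[child_key][sp, sc]
        total += prob
        for key in internal:
            marg[key][assignment[index[key]]] += prob
    loglik = np.log(total)
    marginals = {key: v / total for key, v in marg.items()}
    return float(loglik), marginals
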