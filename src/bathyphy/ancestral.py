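"""Mk-model ancestral-state reconstruction on trees and tree samples.

The model is the one-parameter equal-rates Mk process: a continuous-time
Markov chain on k states whose instantaneous rate between every ordered
state pair is alpha. Its transition probability over a branch of length t
has the closed form

    P_ii(t) = 1/k + (k-1)/k * exp(-k * alpha * t)
    P_ij(t) = 1/k -     1/k * exp(-k * alpha * t)    (i != j)

Likelihoods are computed with Felsenstein's pruning algorithm under a
uniform root prior 1/k; marginal ancestral probabilities combine the usual
downward (subtree) partials with upward (rest-of-tree) partials, which is
equivalent to re-rooting at every node. Reconstructions over a posterior
tree sample are summarised on the maximum clade credibility (MCC) tree by
averaging each clade's marginal vector over the sample trees that contain
that clade.

Habitat is coded 0 = nonchemosynthetic, 1 = hydrothermal vent, 2 = cold
seep, 3 = organic fall; depth is coded 0/1 by whether the shallowest
recorded depth is below 1000 m.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .errors import CodingError, TreeError
from .tables import CharacterData, HABITAT_CLASSES, ReferenceTable
from .trees import PhyloTree, TreeSample, clade_bipartitions

log = logging.getLogger(__name__)

DEPTH_STATES = ("shallower_1000m", "deeper_1000m")


@dataclass(frozen=True)
class MkModel:
    """Equal-rates Mk model: k states, rate `alpha` between each ordered pair."""

    k: int
    alpha: float

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("Mk model needs k >= 2 states")
        if not (self.alpha > 0 and math.isfinite(self.alpha)):
            raise ValueError("alpha must be positive and finite")


def mk_transition_matrix(model: MkModel, t: float) -> np.ndarray:
    """k x k stochastic matrix of the equal-rates Mk chain over branch length t."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    k = model.k
    decay = math.exp(-k * model.alpha * t)
    off = (1.0 - decay) / k
    matrix = np.full((k, k), off)
    np.fill_diagonal(matrix, off + decay)
    return matrix


# ---------------------------------------------------------------------------
# character encodings
# ---------------------------------------------------------------------------

def encode_habitat(refs: ReferenceTable, policy: str = "organic_priority") -> CharacterData:
    """Code the habitat character (k=4) from a reference table.

    States follow the standard coding 0 = nonchemosynthetic, 1 = vent,
    2 = seep, 3 = organic fall. Taxa recorded from several habitat classes
    are resolved by `policy`:

    - ``organic_priority`` (default): organic fall if any organic substrate
      is recorded, else vent, else seep; each resolution is logged.
    - ``strict``: refuse polymorphic taxa with a :class:`CodingError`.
    """
    if policy not in {"organic_priority", "strict"}:
        raise CodingError(f"unknown polymorphism policy {policy!r}")
    assignments: dict[str, int] = {}
    for rec in refs:
        classes = rec.habitats
        if len(classes) == 1:
            state = HABITAT_CLASSES.index(classes[0])
        elif policy == "strict":
            raise CodingError(f"{rec.taxon}: polymorphic habitat {classes}")
        else:
            if "organic_fall" in classes:
                chosen = "organic_fall"
            elif "vent" in classes:
                chosen = "vent"
            elif "seep" in classes:
                chosen = "seep"
            else:
                chosen = classes[0]
            state = HABITAT_CLASSES.index(chosen)
            log.info(
                "habitat polymorphism for %s (%s) resolved to %s",
                rec.taxon, ",".join(classes), chosen,
            )
        assignments[rec.taxon] = state
    return CharacterData(HABITAT_CLASSES, assignments)


def encode_depth(refs: ReferenceTable) -> CharacterData:
    """Code the depth character (k=2): shallowest record < 1000 m -> 0, else 1.

    Exactly 1000 m codes as 1 (deep).
    """
    assignments: dict[str, int] = {}
    for rec in refs:
        if rec.depth_min is None:
            raise CodingError(f"{rec.taxon}: no recorded depth")
        assignments[rec.taxon] = 0 if rec.depth_min < 1000.0 else 1
    return CharacterData(DEPTH_STATES, assignments)


# ---------------------------------------------------------------------------
# pruning likelihood and marginals
# ---------------------------------------------------------------------------

def _as_char_list(chars) -> list[CharacterData]:
    if isinstance(chars, CharacterData):
        return [chars]
    chars = list(chars)
    if not chars:
        raise CodingError("no characters supplied")
    k = chars[0].k
    if any(c.k != k for c in chars):
        raise CodingError("all characters must share one state space size")
    return chars


def _leaf_partial(char: CharacterData, label: str, k: int) -> np.ndarray:
    state = char.state_of(label)
    if state is None:
        return np.ones(k)  # missing taxon: all states possible
    vec = np.zeros(k)
    vec[state] = 1.0
    return vec


def _downward_partials(
    tree: PhyloTree, char: CharacterData, model: MkModel
) -> tuple[dict[dendropy.Node, np.ndarray], dict[dendropy.Node, np.ndarray], float]:
    """Post-order conditional likelihoods.

    Returns (down-partials, per-edge transition matrices keyed by child node,
    log scaling accumulated for numerical stability).
    """
    k = model.k
    down: dict[dendropy.Node, np.ndarray] = {}
    pmats: dict[dendropy.Node, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            down[node] = _leaf_partial(char, node.taxon.label, k)
        else:
            partial = np.ones(k)
            for child in node.child_nodes():
                t = child.edge.length if child.edge.length is not None else 0.0
                pmat = mk_transition_matrix(model, t)
                pmats[child] = pmat
                partial = partial * (pmat @ down[child])
            peak = partial.max()
            if peak <= 0.0:
                return down, pmats, -math.inf
            if peak < 1e-280:
                partial = partial / peak
                log_scale += math.log(peak)
            down[node] = partial
    return down, pmats, log_scale


def pruning_loglik(
    tree: PhyloTree,
    chars: CharacterData | Sequence[CharacterData],
    model: MkModel,
) -> float:
    """Log-likelihood of one or more independent characters on a rooted tree.

    Uniform 1/k root prior; taxa missing from a character are treated as
    all-states-possible partials.
    """
    if not tree.is_rooted:
        raise TreeError("pruning requires a rooted tree")
    total = 0.0
    for char in _as_char_list(chars):
        if char.k != model.k:
            raise CodingError(f"character has k={char.k}, model k={model.k}")
        down, _, log_scale = _downward_partials(tree, char, model)
        if not math.isfinite(log_scale):
            return -math.inf
        root_partial = down[tree.seed_node]
        lik = root_partial.mean()  # uniform prior 1/k
        if lik <= 0.0:
            return -math.inf
        total += math.log(lik) + log_scale
    return total


def marginal_ancestral(
    tree: PhyloTree,
    chars: CharacterData,
    model: MkModel,
) -> dict[frozenset[str], np.ndarray]:
    """Marginal posterior state probabilities for every node.

    Keys are descendant-leaf-label sets (leaves appear as singletons); each
    value is a length-k vector summing to 1. Computed by combining downward
    partials with upward partials, which is equivalent to re-rooting the tree
    at each node in turn.
    """
    if not tree.is_rooted:
        raise TreeError("marginal reconstruction requires a rooted tree")
    if chars.k != model.k:
        raise CodingError(f"character has k={chars.k}, model k={model.k}")
    k = model.k
    down, pmats, _ = _downward_partials(tree, chars, model)
    prior = np.full(k, 1.0 / k)
    up: dict[dendropy.Node, np.ndarray] = {tree.seed_node: prior.copy()}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = node.parent_node
        rest = up[parent].copy()
        for sib in parent.child_nodes():
            if sib is node:
                continue
            rest = rest * (pmats[sib] @ down[sib])
        up[node] = pmats[node].T @ rest
        peak = up[node].max()
        if peak > 0:
            up[node] = up[node] / peak  # scale only; marginals are normalised below
    out: dict[frozenset[str], np.ndarray] = {}
    for node in tree.preorder_node_iter():
        joint = down[node] * up[node]
        total = joint.sum()
        if total <= 0.0:
            raise ValueError("zero likelihood; data impossible under the model")
        key = frozenset(lf.taxon.label for lf in node.leaf_iter())
        out[key] = joint / total
    return out


def estimate_alpha(
    tree: PhyloTree,
    chars: CharacterData | Sequence[CharacterData],
    bounds: tuple[float, float] = (1e-8, 100.0),
) -> MkModel:
    """Maximum-likelihood estimate of the single Mk rate by bounded 1-D search.

    With no variable character pattern the likelihood is monotone decreasing
    in alpha; a warning is emitted and alpha is pinned to the lower bound.
    """
    char_list = _as_char_list(chars)
    k = char_list[0].k
    tip_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    variable = any(
        len({s for t, s in c.assignments.items() if t in tip_labels}) > 1
        for c in char_list
    )
    if not variable:
        warnings.warn(
            "no variable character pattern: alpha pinned to the lower bound",
            stacklevel=2,
        )
        return MkModel(k, bounds[0])

    # optimise on the log scale: a rate spans orders of magnitude, and the
    # likelihood is flat for large alpha, which traps a linear-scale search
    def negloglik(log_alpha: float) -> float:
        return -pruning_loglik(tree, char_list, MkModel(k, math.exp(log_alpha)))

    res = minimize_scalar(
        negloglik,
        bounds=(math.log(bounds[0]), math.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return MkModel(k, float(math.exp(res.x)))


# ---------------------------------------------------------------------------
# tree-sample summarisation
# ---------------------------------------------------------------------------

def clade_frequencies(sample: TreeSample) -> dict[frozenset[str], float]:
    """Weighted frequency of every non-trivial clade across the sample."""
    freqs: dict[frozenset[str], float] = {}
    for tree, w in zip(sample.trees, sample.weights):
        for clade in clade_bipartitions(tree):
            freqs[clade] = freqs.get(clade, 0.0) + float(w)
    return freqs


def mcc_tree(sample: TreeSample) -> PhyloTree:
    """Maximum clade credibility tree: the sample member maximising the sum of
    log clade frequencies; ties broken by first occurrence."""
    freqs = clade_frequencies(sample)
    best, best_score = None, -math.inf
    for tree in sample:
        score = sum(math.log(freqs[c]) for c in clade_bipartitions(tree))
        if score > best_score:
            best, best_score = tree, score
    assert best is not None
    return best


@dataclass(frozen=True)
class CladeSummary:
    """Per-clade summary of a reconstruction averaged over a tree sample."""

    mean_probs: np.ndarray
    clade_frequency: float
    n_trees_used: int


@dataclass(frozen=True)
class AncestralReconstruction:
    """Mean marginal reconstructions mapped onto a summary (MCC) tree."""

    summary_tree: PhyloTree
    state_space: tuple[str, ...]
    per_clade: dict[frozenset[str], CladeSummary]
    per_tree: tuple[dict[frozenset[str], np.ndarray], ...] | None = None

    @property
    def k(self) -> int:
        return len(self.state_space)

    def modal_state(self, clade: frozenset[str], threshold: float = 0.5) -> int | None:
        """Modal state of a clade iff its max mean probability >= threshold."""
        summary = self.per_clade.get(clade)
        if summary is None:
            return None
        best = int(np.argmax(summary.mean_probs))
        return best if summary.mean_probs[best] >= threshold else None

    def to_tsv(self, path: str | Path, header_comments: Mapping[str, object] = ()) -> None:
        with open(path, "w") as fh:
            for key, value in dict(header_comments).items():
                fh.write(f"# {key}={value}\n")
            cols = [f"p_state{i}" for i in range(self.k)]
            fh.write(
                "clade\tclade_frequency\tn_trees_used\t"
                + "\t".join(cols)
                + "\tmodal_state\n"
            )
            for clade in sorted(self.per_clade, key=lambda c: (len(c), sorted(c))):
                s = self.per_clade[clade]
                modal = self.modal_state(clade)
                fh.write(
                    ",".join(sorted(clade))
                    + f"\t{s.clade_frequency:.4f}\t{s.n_trees_used}\t"
                    + "\t".join(f"{p:.6f}" for p in s.mean_probs)
                    + f"\t{'' if modal is None else modal}\n"
                )


def average_over_trees(
    sample: TreeSample,
    chars: CharacterData,
    per_tree_alpha: bool = True,
    model: MkModel | None = None,
    keep_per_tree: bool = False,
) -> AncestralReconstruction:
    """Reconstruct on every tree of the sample and average onto the MCC tree.

    For each internal clade of the MCC tree the marginal vectors of the
    sample trees *containing* that clade are arithmetically averaged
    (renormalised); trees lacking the clade contribute nothing, and
    `n_trees_used` records how many entered each mean. The Mk rate is
    estimated per tree (each sampled tree has its own branch lengths), once
    on the MCC tree (`per_tree_alpha=False`), or fixed via `model`.
    """
    summary = mcc_tree(sample)
    freqs = clade_frequencies(sample)
    shared_model = model
    if shared_model is None and not per_tree_alpha:
        shared_model = estimate_alpha(summary, chars)
    targets = set(clade_bipartitions(summary))
    targets.add(frozenset(lf.taxon.label for lf in summary.seed_node.leaf_iter()))
    sums: dict[frozenset[str], np.ndarray] = {c: np.zeros(chars.k) for c in targets}
    used: dict[frozenset[str], int] = {c: 0 for c in targets}
    per_tree_out: list[dict[frozenset[str], np.ndarray]] = []
    for tree in sample:
        tree_model = shared_model if shared_model is not None else estimate_alpha(tree, chars)
        marginals = marginal_ancestral(tree, chars, tree_model)
        if keep_per_tree:
            per_tree_out.append(marginals)
        for clade in targets:
            vec = marginals.get(clade)
            if vec is not None:
                sums[clade] += vec
                used[clade] += 1
    per_clade: dict[frozenset[str], CladeSummary] = {}
    full = frozenset(lf.taxon.label for lf in summary.seed_node.leaf_iter())
    for clade in targets:
        n = used[clade]
        if n == 0:
            continue  # cannot happen for MCC clades: the MCC tree is in the sample
        mean = sums[clade] / n
        mean = mean / mean.sum()
        per_clade[clade] = CladeSummary(
            mean_probs=mean,
            clade_frequency=1.0 if clade == full else freqs.get(clade, 0.0),
            n_trees_used=n,
        )
    return AncestralReconstruction(
        summary_tree=summary,
        state_space=tuple(chars.state_space),
        per_clade=per_clade,
        per_tree=tuple(per_tree_out) if keep_per_tree else None,
    )


# ---------------------------------------------------------------------------
# transition counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionSummary:
    """Directed state changes along the edges of a summary tree."""

    counts: dict[tuple[int, int], int]
    unresolved_edges: int
    edges: tuple[tuple[frozenset[str], frozenset[str], int, int], ...] = ()
    state_space: tuple[str, ...] = ()

    def total(self) -> int:
        return sum(self.counts.values())


def count_transitions(
    recon: AncestralReconstruction,
    chars: CharacterData,
    modal_threshold: float = 0.5,
) -> TransitionSummary:
    """Count directed modal-state changes along edges of the summary tree.

    Every node gets its modal state iff its max mean probability is at least
    `modal_threshold` (leaves use their observed states); edges whose two
    resolved endpoint states differ increment ``counts[(parent, child)]``;
    edges with an unresolved endpoint are tallied separately.
    """
    tree = recon.summary_tree
    states: dict[dendropy.Node, int | None] = {}
    keys: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.preorder_node_iter():
        key = frozenset(lf.taxon.label for lf in node.leaf_iter())
        keys[node] = key
        if node.is_leaf():
            states[node] = chars.state_of(node.taxon.label)
        else:
            states[node] = recon.modal_state(key, modal_threshold)
    counts: dict[tuple[int, int], int] = {}
    edges: list[tuple[frozenset[str], frozenset[str], int, int]] = []
    unresolved = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        ps, cs = states[node.parent_node], states[node]
        if ps is None or cs is None:
            unresolved += 1
        elif ps != cs:
            counts[(ps, cs)] = counts.get((ps, cs), 0) + 1
            edges.append((keys[node.parent_node], keys[node], ps, cs))
    return TransitionSummary(
        counts=counts,
        unresolved_edges=unresolved,
        edges=tuple(edges),
        state_space=tuple(recon.state_space),
    )


def annotate_tree(recon: AncestralReconstruction) -> PhyloTree:
    """Clone of the summary tree with per-node probability annotations (for NEXUS)."""
    tree = recon.summary_tree.clone(depth=1)
    for node in tree.preorder_node_iter():
        key = frozenset(lf.taxon.label for lf in node.leaf_iter())
        summary = recon.per_clade.get(key)
        if summary is not None:
            probs = ",".join(f"{p:.4f}" for p in summary.mean_probs)
            node.annotations.add_new("state_probs", f"{{{probs}}}")
    return tree
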