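"""Phylogenetic trees and tree samples.

Trees are `dendropy.Tree` objects (branch lengths in expected substitutions
per site); this module adds the I/O, rooting and clade utilities the
assignment and ancestral-state machinery needs. Internal node labels in
Newick input are treated as support metadata, never as taxon names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np

from .errors import (
    EmptyInputError,
    NegativeBranchLengthError,
    NewickError,
    NoSisterError,
    TreeError,
    UnknownTaxonError,
)

PhyloTree = dendropy.Tree


def _validate(tree: PhyloTree) -> PhyloTree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate leaf labels")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and (edge.length < 0 or not np.isfinite(edge.length)):
            raise NegativeBranchLengthError(
                f"branch length {edge.length!r} is negative or non-finite"
            )
    return tree


def parse_newick(text: str, rooted: bool | None = None) -> PhyloTree:
    """Parse a single Newick string; `rooted=None` keeps the file's own flag."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy's parse errors form no single class
        raise NewickError(f"cannot parse Newick: {exc}") from exc
    if rooted is not None:
        tree.is_rooted = rooted
    return _validate(tree)


def read_newick(path: str | Path, rooted: bool | None = None) -> PhyloTree:
    return parse_newick(Path(path).read_text(), rooted=rooted)


def write_newick(tree: PhyloTree, path: str | Path | None = None) -> str:
    """Serialise to Newick (with rooting token); returns the string."""
    text = tree.as_string(schema="newick", unquoted_underscores=True)
    if path is not None:
        Path(path).write_text(text)
    return text


@dataclass
class TreeSample:
    """An ordered collection of trees over one taxon set, e.g. a posterior sample."""

    trees: list[PhyloTree]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.trees:
            raise EmptyInputError("tree sample is empty")
        if self.weights is None:
            self.weights = np.full(len(self.trees), 1.0 / len(self.trees))
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.trees):
            raise TreeError("one weight per tree required")
        if not np.isclose(self.weights.sum(), 1.0):
            raise TreeError("tree weights must sum to 1")
        ref = leaf_set(self.trees[0])
        for t in self.trees[1:]:
            if leaf_set(t) != ref:
                raise TreeError("all trees in a sample must share one leaf label set")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


def read_tree_sample(path: str | Path, rooted: bool | None = True) -> TreeSample:
    """Read a one-tree-per-line Newick file as a TreeSample (uniform weights)."""
    try:
        trees = dendropy.TreeList.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickError(f"cannot parse tree sample: {exc}") from exc
    if rooted is not None:
        for t in trees:
            t.is_rooted = rooted
    for t in trees:
        _validate(t)
    return TreeSample(list(trees))


def write_tree_sample(sample: TreeSample, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tree in sample:
            fh.write(write_newick(tree).strip() + "\n")


def leaf_set(tree: PhyloTree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def clone(tree: PhyloTree) -> PhyloTree:
    return tree.clone(depth=1)


def root_with_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Root on the edge subtending `outgroup`, splitting that edge 50/50.

    Leaf-to-leaf path lengths are preserved. Idempotent when the tree is
    already rooted on the outgroup's edge.
    """
    new = clone(tree)
    node = next(
        (lf for lf in new.leaf_node_iter() if lf.taxon.label == outgroup), None
    )
    if node is None:
        raise UnknownTaxonError(f"outgroup {outgroup!r} not in tree")
    parent = node.parent_node
    if (
        new.is_rooted
        and parent is new.seed_node
        and len(parent.child_nodes()) == 2
    ):
        return new
    length = node.edge.length if node.edge.length is not None else 0.0
    new.reroot_at_edge(node.edge, length1=length / 2.0, length2=length / 2.0)
    new.is_rooted = True
    new.suppress_unifurcations()
    return new


def clade_bipartitions(tree: PhyloTree) -> set[frozenset[str]]:
    """Leaf-label sets of the internal nodes, excluding singletons and the full set."""
    if not tree.is_rooted:
        raise TreeError("clade_bipartitions requires a rooted tree")
    full = leaf_set(tree)
    clades: set[frozenset[str]] = set()
    for node in tree.preorder_internal_node_iter():
        ls = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(ls) < len(full):
            clades.add(ls)
    return clades


def node_clades(tree: PhyloTree) -> dict[frozenset[str], dendropy.Node]:
    """Map descendant-leaf-set -> node, for every node (leaves included)."""
    out: dict[frozenset[str], dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        out[frozenset(lf.taxon.label for lf in node.leaf_iter())] = node
    return out


def sister_group(tree: PhyloTree, target: str | Iterable[str]) -> frozenset[str]:
    """Leaf set of the sibling subtree of the smallest clade containing `target`."""
    if not tree.is_rooted:
        raise TreeError("sister_group requires a rooted tree")
    labels = {target} if isinstance(target, str) else set(target)
    present = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = labels - present
    if missing:
        raise UnknownTaxonError(f"taxa not in tree: {sorted(missing)}")
    if len(labels) == 1:
        node = next(lf for lf in tree.leaf_node_iter() if lf.taxon.label in labels)
    else:
        node = tree.mrca(taxon_labels=sorted(labels))
    parent = node.parent_node
    if parent is None:
        raise NoSisterError("target clade is the whole tree")
    sisters: set[str] = set()
    for child in parent.child_nodes():
        if child is not node:
            sisters.update(lf.taxon.label for lf in child.leaf_iter())
    return frozenset(sisters)


def leaf_path_lengths(tree: PhyloTree) -> dict[frozenset[str], float]:
    """All-pairs leaf-to-leaf path lengths (rooting-invariant)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(pdm.taxon_iter())
    out: dict[frozenset[str], float] = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            out[frozenset({a.label, b.label})] = pdm.patristic_distance(a, b)
    return out
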