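"""Synthetic data with the statistical structure the analysis assumes.

Generators for: Yule trees; pseudo-posterior tree samples (NNI topology
moves plus log-normal branch-length jitter around a true tree — a stand-in
for an MCMC sample, not a calibrated posterior); nucleotide alignments under
GTR+I+Gamma; discrete characters under the equal-rates Mk process (with the
true internal states retained for recovery tests); deterministic state
paintings; and a barcode reference fixture whose within-genus K2P distances
sit below and between-genus distances above a chosen threshold.

Every generator is reproducible for a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import yaml
from dendropy.simulate import treesim
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from .alignment import MultiLocusAlignment, subset_taxa
from .ancestral import (
    AncestralReconstruction,
    CladeSummary,
    MkModel,
    mk_transition_matrix,
)
from .distances import pairwise_matrix
from .errors import RecipeError, TreeError
from .tables import CharacterData, HABITAT_CLASSES, ReferenceRecord, ReferenceTable
from .trees import PhyloTree, TreeSample, clone

_NUCS = np.array(list("ACGT"))


@dataclass(frozen=True)
class SubstitutionModel:
    """GTR+I+Gamma: 6 exchangeabilities (AC,AG,AT,CG,CT,GT), base frequencies,
    proportion of invariant sites and a discretised Gamma over site rates."""

    exchangeabilities: tuple[float, ...] = (1.0,) * 6
    base_frequencies: tuple[float, ...] = (0.25,) * 4
    p_invariant: float = 0.0
    gamma_shape: float | None = None
    n_rate_categories: int = 4

    def __post_init__(self) -> None:
        if len(self.exchangeabilities) != 6 or any(
            r <= 0 for r in self.exchangeabilities
        ):
            raise RecipeError("need 6 positive exchangeability parameters")
        pi = np.asarray(self.base_frequencies, float)
        if len(pi) != 4 or np.any(pi <= 0) or not np.isclose(pi.sum(), 1.0):
            raise RecipeError("base frequencies must be 4 positive values summing to 1")
        if not 0.0 <= self.p_invariant <= 1.0:
            raise RecipeError("p_invariant must lie in [0, 1]")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise RecipeError("gamma shape must be positive")
        if self.n_rate_categories < 1:
            raise RecipeError("need at least one rate category")

    def rate_matrix(self) -> np.ndarray:
        """GTR generator Q normalised to one expected substitution per unit time."""
        pi = np.asarray(self.base_frequencies, float)
        ac, ag, at, cg, ct, gt = self.exchangeabilities
        r = np.array(
            [[0, ac, ag, at], [ac, 0, cg, ct], [ag, cg, 0, gt], [at, ct, gt, 0]],
            float,
        )
        q = r * pi[None, :]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    def site_rate_categories(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, probabilities) of the site-rate mixture, mean rate 1.

        A site is invariant (rate 0) with probability I; otherwise it draws
        one of `n_rate_categories` equal-probability discrete-Gamma rates
        (category medians, renormalised), scaled by 1/(1-I) so the overall
        expectation stays 1 and branch lengths keep their substitutions-per-
        site meaning.
        """
        if self.p_invariant >= 1.0:
            return np.array([0.0]), np.array([1.0])
        n = self.n_rate_categories
        if self.gamma_shape is None:
            cats = np.ones(1)
            n = 1
        else:
            quantiles = (2 * np.arange(n) + 1) / (2 * n)
            cats = gamma_dist.ppf(quantiles, a=self.gamma_shape,
                                  scale=1.0 / self.gamma_shape)
            cats = cats / cats.mean()
        rates = [0.0] if self.p_invariant > 0 else []
        probs = [self.p_invariant] if self.p_invariant > 0 else []
        scale = 1.0 / (1.0 - self.p_invariant)
        for c in cats:
            rates.append(c * scale)
            probs.append((1.0 - self.p_invariant) / n)
        return np.asarray(rates), np.asarray(probs)


def simulate_yule_tree(
    n_taxa: int, birth_rate: float = 1.0, seed: int = 0
) -> PhyloTree:
    """Rooted binary pure-birth tree with `n_taxa` extant tips."""
    if n_taxa < 3:
        raise TreeError("need at least 3 taxa")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=rng,
    )
    tree.is_rooted = True
    # drop the root stem so total path lengths start at the first split
    tree.seed_node.edge.length = None
    return tree


def _random_nni(tree: PhyloTree, rng: random.Random) -> None:
    """One random nearest-neighbour interchange, in place."""
    internal_edges = [
        nd for nd in tree.preorder_internal_node_iter()
        if nd.parent_node is not None
    ]
    if not internal_edges:
        return
    child = rng.choice(internal_edges)
    parent = child.parent_node
    siblings = [c for c in parent.child_nodes() if c is not child]
    grandchildren = child.child_nodes()
    if not siblings or len(grandchildren) < 2:
        return
    s = rng.choice(siblings)
    g = rng.choice(grandchildren)
    parent.remove_child(s)
    child.remove_child(g)
    parent.add_child(g)
    child.add_child(s)


def perturb_tree_sample(
    true_tree: PhyloTree,
    n_trees: int,
    nni_moves: int = 1,
    length_jitter_sigma: float = 0.1,
    seed: int = 0,
) -> TreeSample:
    """Pseudo-posterior sample around a true tree.

    Each tree is an independent copy of `true_tree` after `nni_moves` random
    NNI rearrangements and per-branch log-normal length multipliers with
    log-scale standard deviation `length_jitter_sigma`. Zero moves and zero
    sigma reproduce the true tree exactly.
    """
    rng = random.Random(seed)
    nrng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_trees):
        t = clone(true_tree)
        for _ in range(nni_moves):
            _random_nni(t, rng)
        if length_jitter_sigma > 0:
            for edge in t.preorder_edge_iter():
                if edge.length is not None:
                    edge.length = float(
                        edge.length * nrng.lognormal(0.0, length_jitter_sigma)
                    )
        trees.append(t)
    return TreeSample(trees)


def simulate_alignment(
    tree: PhyloTree,
    model: SubstitutionModel,
    length: int,
    seed: int = 0,
    partition_name: str = "sim",
) -> MultiLocusAlignment:
    """Evolve `length` sites along `tree` under GTR+I+Gamma.

    The root sequence is drawn from the stationary base frequencies; each
    site carries a rate multiplier from the invariant/Gamma mixture and
    evolves along every branch by the matrix exponential of the scaled GTR
    generator.
    """
    if length < 1:
        raise RecipeError("alignment length must be >= 1")
    rng = np.random.default_rng(seed)
    q = model.rate_matrix()
    pi = np.asarray(model.base_frequencies)
    rates, probs = model.site_rate_categories()
    site_cat = rng.choice(len(rates), size=length, p=probs)

    leaves: dict[str, np.ndarray] = {}
    root_states = rng.choice(4, size=length, p=pi)
    states: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = root_states
        else:
            t = node.edge.length if node.edge.length is not None else 0.0
            parent_states = states[node.parent_node]
            child = parent_states.copy()
            for ci, rate in enumerate(rates):
                idx = np.nonzero(site_cat == ci)[0]
                if len(idx) == 0 or rate == 0.0 or t == 0.0:
                    continue
                pmat = expm(q * (t * rate))
                pmat = np.clip(pmat, 0.0, None)
                pmat = pmat / pmat.sum(axis=1, keepdims=True)
                cum = pmat.cumsum(axis=1)
                u = rng.random(len(idx))
                child[idx] = (u[:, None] > cum[parent_states[idx]]).sum(axis=1)
            states[node] = child
        if node.is_leaf():
            leaves[node.taxon.label] = states[node]

    taxa = tuple(leaves)
    seqs = tuple("".join(_NUCS[s]) for s in leaves.values())
    return MultiLocusAlignment(taxa, seqs, ((partition_name, 0, length),))


def simulate_character(
    tree: PhyloTree,
    model: MkModel,
    root_state: int | None = None,
    seed: int = 0,
) -> tuple[CharacterData, PhyloTree]:
    """Evolve one discrete character under the Mk model.

    Returns the tip data and a painted copy of the tree whose every node
    carries its true simulated state in ``node.state`` — the ground truth for
    reconstruction-recovery experiments.
    """
    rng = np.random.default_rng(seed)
    painted = clone(tree)
    k = model.k
    assignments: dict[str, int] = {}
    for node in painted.preorder_node_iter():
        if node.parent_node is None:
            node.state = int(rng.integers(k)) if root_state is None else int(root_state)
        else:
            t = node.edge.length if node.edge.length is not None else 0.0
            pmat = mk_transition_matrix(model, t)
            node.state = int(rng.choice(k, p=pmat[node.parent_node.state]))
        if node.is_leaf():
            assignments[node.taxon.label] = node.state
    chars = CharacterData(tuple(str(i) for i in range(k)), assignments)
    return chars, painted


def paint_states(
    tree: PhyloTree,
    root_state: int,
    shifts: Mapping[frozenset[str] | tuple[str, ...], int] = (),
) -> PhyloTree:
    """Deterministically paint states on a tree: every node inherits its
    parent's state unless its descendant leaf set is named in `shifts`."""
    shift_map = {frozenset(k): v for k, v in dict(shifts).items()}
    painted = clone(tree)
    for node in painted.preorder_node_iter():
        key = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if key in shift_map:
            node.state = shift_map[key]
        elif node.parent_node is None:
            node.state = root_state
        else:
            node.state = node.parent_node.state
    return painted


def painted_tip_characters(
    painted: PhyloTree, state_space: Sequence[str]
) -> CharacterData:
    """Read tip states off a painted tree."""
    return CharacterData(
        tuple(state_space),
        {lf.taxon.label: lf.state for lf in painted.leaf_node_iter()},
    )


def painted_change_count(painted: PhyloTree) -> dict[tuple[int, int], int]:
    """Directed (parent_state, child_state) change counts on a painted tree."""
    counts: dict[tuple[int, int], int] = {}
    for node in painted.preorder_node_iter():
        if node.parent_node is None:
            continue
        ps, cs = node.parent_node.state, node.state
        if ps != cs:
            counts[(ps, cs)] = counts.get((ps, cs), 0) + 1
    return counts


def painting_to_reconstruction(
    painted: PhyloTree, state_space: Sequence[str]
) -> AncestralReconstruction:
    """One-hot reconstruction equivalent to a noiseless painting (for audits)."""
    k = len(state_space)
    per_clade: dict[frozenset[str], CladeSummary] = {}
    for node in painted.preorder_internal_node_iter():
        key = frozenset(lf.taxon.label for lf in node.leaf_iter())
        probs = np.zeros(k)
        probs[node.state] = 1.0
        per_clade[key] = CladeSummary(probs, 1.0, 1)
    return AncestralReconstruction(
        summary_tree=painted,
        state_space=tuple(state_space),
        per_clade=per_clade,
    )


# ---------------------------------------------------------------------------
# barcode reference fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceFixture:
    """A synthetic barcode study: reference table + alignment, queries, truth."""

    refs: ReferenceTable
    ref_alignment: MultiLocusAlignment
    queries: MultiLocusAlignment
    truth: dict[str, str]
    tree: PhyloTree


def _fixture_tree(
    n_genera: int,
    species_per_genus: int,
    within_d: float,
    between_d: float,
    query_species: Sequence[tuple[int, int, str]],
) -> PhyloTree:
    """Two-level genus/species tree with query tips attached to their sources."""
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.is_rooted = True
    genus_depth = max(between_d - within_d, 0.0) / 2.0
    tip_depth = within_d / 2.0
    queries_by_species: dict[tuple[int, int], list[str]] = {}
    for gi, si, label in query_species:
        queries_by_species.setdefault((gi, si), []).append(label)
    for gi in range(n_genera):
        genus_node = tree.seed_node.new_child(edge_length=genus_depth)
        for si in range(species_per_genus):
            ref_label = f"Genus{gi + 1}_sp{si + 1}"
            qlabels = queries_by_species.get((gi, si), [])
            if qlabels:
                stem = genus_node.new_child(edge_length=tip_depth / 2.0)
                ref_tip = stem.new_child(edge_length=tip_depth / 2.0)
                for q in qlabels:
                    qt = stem.new_child(edge_length=tip_depth / 2.0)
                    qt.taxon = taxon_ns.new_taxon(q)
            else:
                ref_tip = genus_node.new_child(edge_length=tip_depth)
            ref_tip.taxon = taxon_ns.new_taxon(ref_label)
    return tree


def _realized_distances(
    aln: MultiLocusAlignment, ref_taxa: Sequence[str]
) -> tuple[float, float, float]:
    """(mean within-genus, mean between-genus, fraction undefined) among references."""
    sub = subset_taxa(aln, ref_taxa)
    dm = pairwise_matrix(sub, metric="k2p")
    within, between, bad = [], [], 0
    for i, a in enumerate(dm.taxa):
        for j in range(i + 1, len(dm.taxa)):
            b = dm.taxa[j]
            val = dm.d[i, j]
            if not np.isfinite(val):
                bad += 1
                continue
            if a.split("_")[0] == b.split("_")[0]:
                within.append(val)
            else:
                between.append(val)
    n_pairs = len(within) + len(between) + bad
    return (
        float(np.mean(within)) if within else 0.0,
        float(np.mean(between)) if between else 0.0,
        bad / n_pairs if n_pairs else 0.0,
    )


def make_reference_fixture(
    n_genera: int = 3,
    species_per_genus: int = 4,
    within_d: float = 0.01,
    between_d: float = 0.10,
    seed: int = 0,
    n_queries: int | None = None,
    query_genera: Sequence[int] | None = None,
    n_sites: int = 660,
    model: SubstitutionModel | None = None,
    max_calibration_rounds: int = 3,
) -> ReferenceFixture:
    """Generate a barcode reference study with controlled K2P structure.

    Sequences evolve on a two-level genus/species tree whose branch lengths
    are rescaled empirically (up to `max_calibration_rounds` rounds) so the
    realised mean within-genus and between-genus K2P distances land within
    ~20% of the requested values. Queries are conspecific tips of reference
    species (round-robin over `query_genera`, default all), with their true
    genus retained for accuracy scoring. Habitats cycle over the four habitat
    classes and depth ranges straddle the 1000 m cut.
    """
    if between_d < within_d:
        raise RecipeError("between_d must be at least within_d")
    if between_d > 1.0:
        raise RecipeError(f"between_d={between_d} would saturate K2P")
    if model is None:
        model = SubstitutionModel()
    if query_genera is None:
        query_genera = list(range(n_genera))
    if n_queries is None:
        n_queries = len(query_genera) * species_per_genus
    slots = [
        (gi, si)
        for si in range(species_per_genus)
        for gi in query_genera
    ]
    query_species = [
        (*slots[i % len(slots)], f"query{i + 1}") for i in range(n_queries)
    ]
    tree = _fixture_tree(n_genera, species_per_genus, within_d, between_d, query_species)
    ref_taxa = [
        f"Genus{gi + 1}_sp{si + 1}"
        for gi in range(n_genera)
        for si in range(species_per_genus)
    ]

    aln = simulate_alignment(tree, model, n_sites, seed=seed, partition_name="COI")
    if within_d > 0 or between_d > 0:
        for round_ in range(max_calibration_rounds):
            got_within, got_between, frac_bad = _realized_distances(aln, ref_taxa)
            if frac_bad > 0.1:
                raise RecipeError("requested distances saturate the K2P correction")
            ok_within = within_d == 0 or abs(got_within - within_d) <= 0.2 * within_d
            ok_between = between_d == 0 or abs(got_between - between_d) <= 0.2 * between_d
            if ok_within and ok_between:
                break
            scale = between_d / got_between if got_between > 0 else 1.0
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    edge.length = float(edge.length * scale)
            aln = simulate_alignment(
                tree, model, n_sites, seed=seed + round_ + 1, partition_name="COI"
            )

    rng = np.random.default_rng(seed + 10_000)
    records = []
    for idx, taxon in enumerate(ref_taxa):
        habitat = HABITAT_CLASSES[idx % len(HABITAT_CLASSES)]
        if idx % 2 == 0:
            depth_min = float(rng.uniform(100, 900))
        else:
            depth_min = float(rng.uniform(1100, 3500))
        records.append(
            ReferenceRecord(
                taxon=taxon,
                genus=taxon.split("_")[0],
                habitats=(habitat,),
                depth_min=round(depth_min),
                depth_max=round(depth_min + float(rng.uniform(50, 500))),
                sequence_ids={"COI": f"SYN{idx:05d}"},
            )
        )
    refs = ReferenceTable(tuple(records))
    ref_aln = subset_taxa(aln, ref_taxa)
    qlabels = [label for _, _, label in query_species]
    queries = subset_taxa(aln, qlabels)
    truth = {label: f"Genus{gi + 1}" for gi, _, label in query_species}
    return ReferenceFixture(refs, ref_aln, queries, truth, tree)


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationRecipe:
    """Plain-file description of a full synthetic study."""

    seed: int
    n_taxa: int = 20
    birth_rate: float = 1.0
    tree_depth: float | None = None
    partition_lengths: tuple[int, ...] = (660,)
    model: SubstitutionModel = field(default_factory=SubstitutionModel)
    character_model: MkModel = field(default_factory=lambda: MkModel(4, 0.1))
    n_sample_trees: int = 100
    nni_moves: int = 1
    length_jitter_sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.n_taxa < 3 or self.n_sample_trees < 1:
            raise RecipeError("counts must be positive")
        if any(l < 1 for l in self.partition_lengths):
            raise RecipeError("partition lengths must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationRecipe":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in raw:
            raise RecipeError("recipe must declare a seed")
        if "model" in raw:
            raw["model"] = SubstitutionModel(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["model"].items()
            })
        if "character_model" in raw:
            raw["character_model"] = MkModel(**raw["character_model"])
        if "partition_lengths" in raw:
            raw["partition_lengths"] = tuple(raw["partition_lengths"])
        return cls(**raw)


def scale_tree_depth(tree: PhyloTree, depth: float) -> PhyloTree:
    """Rescale branch lengths so the maximum root-to-tip distance equals `depth`."""
    new = clone(tree)
    height = max(
        lf.distance_from_root() for lf in new.leaf_node_iter()
    )
    if height <= 0:
        raise TreeError("tree has zero height")
    factor = depth / height
    for edge in new.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(edge.length * factor)
    return new
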