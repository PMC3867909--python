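import itertools
import math

import numpy as np
import pytest

import bathyphy as bp
from bathyphy.ancestral import (
    DEPTH_STATES,
    annotate_tree,
    clade_frequencies,
    count_transitions,
    estimate_alpha,
    mcc_tree,
)
from bathyphy.errors import CodingError
from bathyphy.simulate import (
    paint_states,
    painted_change_count,
    painted_tip_characters,
    painting_to_reconstruction,
)
from bathyphy.tables import CharacterData, HABITAT_CLASSES, ReferenceRecord, ReferenceTable, parse_habitats
from bathyphy.trees import TreeSample, parse_newick

from _oracles import brute_force_likelihoods, build_tree, expm_transition_matrix


def _record(taxon, habitat, depth_min, depth_max=None, genus="G"):
    return ReferenceRecord(
        taxon, genus, parse_habitats(habitat), depth_min,
        depth_max if depth_max is not None else depth_min,
    )


class TestEncodings:
    def test_habitat_coding_follows_standard_zero_to_three(self):
        refs = ReferenceTable(
            (
                _record("Modiolus_modiolus", "Intertidal subtidal", 10, 300),
                _record("Tamu_fisheri", "Seep", 546, 650),
                _record("Benthomodiolus_lignocola", "Wood, bone", 1180),
                _record("Vulcanidas_insolatus", "Vent", 140, 504),
            )
        )
        chars = bp.encode_habitat(refs)
        assert chars.state_space == HABITAT_CLASSES
        assert chars.assignments == {
            "Modiolus_modiolus": 0,
            "Tamu_fisheri": 2,
            "Benthomodiolus_lignocola": 3,
            "Vulcanidas_insolatus": 1,
        }

    def test_polymorphic_habitat_organic_priority(self):
        refs = ReferenceTable((_record("Idas_washingtonius", "Vent, wood, bone", 960, 1910),))
        assert bp.encode_habitat(refs).assignments["Idas_washingtonius"] == 3
        with pytest.raises(CodingError):
            bp.encode_habitat(refs, policy="strict")

    def test_depth_split_at_1000m_on_shallowest_record(self):
        refs = ReferenceTable(
            (
                _record("Modiolus_modiolus", "Intertidal subtidal", 10, 300),
                _record("B_brevior", "Vent", 3589),
                _record("Idas_washingtonius", "Vent, wood, bone", 960, 1910),
                _record("exactly_1km", "Vent", 1000),
            )
        )
        chars = bp.encode_depth(refs)
        assert chars.state_space == DEPTH_STATES
        assert chars.assignments == {
            "Modiolus_modiolus": 0,
            "B_brevior": 1,
            "Idas_washingtonius": 0,  # shallowest record 960 < 1000
            "exactly_1km": 1,
        }

    def test_missing_depth_rejected(self):
        refs = ReferenceTable((_record("x", "Vent", None),))
        with pytest.raises(CodingError):
            bp.encode_depth(refs)


class TestMkTransitionMatrix:
    def test_zero_branch_is_identity(self):
        assert np.allclose(bp.mk_transition_matrix(bp.MkModel(3, 2.0), 0.0), np.eye(3))

    def test_long_branch_reaches_uniform(self):
        p = bp.mk_transition_matrix(bp.MkModel(4, 1.0), 1e6)
        assert np.allclose(p, 0.25)

    @pytest.mark.parametrize(
        "k,alpha,t", list(itertools.product([2, 3, 4], [0.3, 1.0], [0.05, 0.4, 2.0]))
    )
    def test_matches_matrix_exponential(self, k, alpha, t):
        ours = bp.mk_transition_matrix(bp.MkModel(k, alpha), t)
        assert np.abs(ours - expm_transition_matrix(k, alpha, t)).max() <= 1e-10

    def test_rows_sum_to_one_and_chapman_kolmogorov(self):
        model = bp.MkModel(4, 0.8)
        for t in [0.0, 0.1, 1.3, 7.0]:
            assert np.allclose(bp.mk_transition_matrix(model, t).sum(axis=1), 1.0)
        p1 = bp.mk_transition_matrix(model, 0.3)
        p2 = bp.mk_transition_matrix(model, 0.9)
        p12 = bp.mk_transition_matrix(model, 1.2)
        assert np.abs(p1 @ p2 - p12).max() <= 1e-10

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            bp.mk_transition_matrix(bp.MkModel(2, 1.0), -0.1)


class TestPruning:
    def test_two_leaf_closed_form(self):
        tree = parse_newick("(A:0.1,B:0.1);", rooted=True)
        chars = CharacterData(("0", "1"), {"A": 0, "B": 0})
        model = bp.MkModel(2, 1.0)
        p = bp.mk_transition_matrix(model, 0.1)
        expected = 0.5 * (p[0, 0] ** 2 + p[1, 0] ** 2)
        assert bp.pruning_loglik(tree, chars, model) == pytest.approx(math.log(expected), abs=1e-12)

    def test_zero_branch_lengths_give_one_over_k(self):
        tree = parse_newick("((A:0.0,B:0.0):0.0,(C:0.0,D:0.0):0.0);", rooted=True)
        chars = CharacterData(("0", "1", "2"), {t: 1 for t in "ABCD"})
        assert bp.pruning_loglik(tree, chars, bp.MkModel(3, 0.5)) == pytest.approx(math.log(1 / 3))

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_brute_force_on_random_six_leaf_trees(self, k, rng):
        from _oracles import enumerate_rooted_topologies

        labels = tuple("ABCDEF")
        topologies = enumerate_rooted_topologies(labels)
        for seed in range(5):
            topo = topologies[int(rng.integers(len(topologies)))]
            lengths = _random_lengths(topo, rng)
            tree = build_tree(topo, lengths)
            chars = CharacterData(
                tuple(str(i) for i in range(k)),
                {t: int(rng.integers(k)) for t in labels},
            )
            model = bp.MkModel(k, float(rng.uniform(0.2, 1.5)))
            expected, _ = brute_force_likelihoods(topo, lengths, chars, model)
            assert bp.pruning_loglik(tree, chars, model) == pytest.approx(expected, abs=1e-10)

    def test_missing_taxon_treated_as_all_states_possible(self):
        tree = parse_newick("((A:0.1,B:0.2):0.1,C:0.3);", rooted=True)
        full = CharacterData(("0", "1"), {"A": 0, "B": 1, "C": 0})
        partial = CharacterData(("0", "1"), {"A": 0, "B": 1})
        model = bp.MkModel(2, 0.7)
        # marginalising C's state by direct summation over its two values
        total = sum(
            math.exp(
                bp.pruning_loglik(
                    tree, CharacterData(("0", "1"), {**partial.assignments, "C": s}), model
                )
            )
            for s in (0, 1)
        )
        assert bp.pruning_loglik(tree, partial, model) == pytest.approx(math.log(total), abs=1e-10)
        assert bp.pruning_loglik(tree, full, model) < bp.pruning_loglik(tree, partial, model)


def _random_lengths(topo, rng):
    from _oracles import topology_clade_keys

    return {key: float(rng.uniform(0.02, 1.0)) for key in topology_clade_keys(topo)}


class TestMarginals:
    def test_symmetric_two_leaf_root_is_uniform(self):
        tree = parse_newick("(A:0.3,B:0.3);", rooted=True)
        chars = CharacterData(("0", "1"), {"A": 0, "B": 1})
        marg = bp.marginal_ancestral(tree, chars, bp.MkModel(2, 1.0))
        assert np.allclose(marg[frozenset({"A", "B"})], [0.5, 0.5])

    def test_star_like_tree_concentrates_on_observed_state(self):
        tree = parse_newick("((A:0.01,B:0.01):0.01,(C:0.01,D:0.01):0.01);", rooted=True)
        chars = CharacterData(("0", "1", "2"), {t: 2 for t in "ABCD"})
        marg = bp.marginal_ancestral(tree, chars, bp.MkModel(3, 1.0))
        assert marg[frozenset("ABCD")][2] > 0.99

    @pytest.mark.parametrize("k", [2, 4])
    def test_matches_brute_force_enumeration(self, k, rng):
        from _oracles import enumerate_rooted_topologies

        labels = tuple("ABCDEF")
        topologies = enumerate_rooted_topologies(labels)
        for seed in range(4):
            topo = topologies[int(rng.integers(len(topologies)))]
            lengths = _random_lengths(topo, rng)
            tree = build_tree(topo, lengths)
            chars = CharacterData(
                tuple(str(i) for i in range(k)),
                {t: int(rng.integers(k)) for t in labels},
            )
            model = bp.MkModel(k, float(rng.uniform(0.2, 1.5)))
            _, expected = brute_force_likelihoods(topo, lengths, chars, model)
            marg = bp.marginal_ancestral(tree, chars, model)
            for key, vec in expected.items():
                assert np.abs(marg[key] - vec).max() <= 1e-10

    def test_vectors_sum_to_one_and_state_relabeling_equivariance(self, yule_tree, rng):
        k = 4
        labels = [lf.taxon.label for lf in yule_tree.leaf_node_iter()]
        states = {t: int(rng.integers(k)) for t in labels}
        chars = CharacterData(tuple("wxyz"), states)
        model = bp.MkModel(k, 0.5)
        marg = bp.marginal_ancestral(yule_tree, chars, model)
        assert all(abs(v.sum() - 1.0) <= 1e-9 for v in marg.values())
        perm = [2, 0, 3, 1]
        permuted = CharacterData(tuple("wxyz"), {t: perm[s] for t, s in states.items()})
        marg_p = bp.marginal_ancestral(yule_tree, permuted, model)
        for key, vec in marg.items():
            expected = np.empty(k)
            for s in range(k):
                expected[perm[s]] = vec[s]
            assert np.allclose(marg_p[key], expected, atol=1e-12)


class TestEstimateAlpha:
    def test_invariant_tips_pin_alpha_to_lower_bound(self):
        tree = parse_newick("((A:0.1,B:0.1):0.1,C:0.2);", rooted=True)
        chars = CharacterData(("0", "1"), {t: 0 for t in "ABC"})
        with pytest.warns(UserWarning):
            model = estimate_alpha(tree, chars)
        assert model.alpha == pytest.approx(1e-8)

    def test_optimum_beats_halved_and_doubled_rate(self, yule_tree):
        chars, _ = bp.simulate_character(yule_tree, bp.MkModel(4, 0.5), seed=5)
        extra = [bp.simulate_character(yule_tree, bp.MkModel(4, 0.5), seed=s)[0] for s in (6, 7)]
        char_list = [chars] + extra
        fit = estimate_alpha(yule_tree, char_list)
        best = bp.pruning_loglik(yule_tree, char_list, fit)
        for factor in (0.5, 2.0):
            other = bp.MkModel(4, fit.alpha * factor)
            assert best >= bp.pruning_loglik(yule_tree, char_list, other) - 1e-9


class TestMccTree:
    def test_sample_of_identical_trees_returns_that_topology(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);", rooted=True)
        sample = TreeSample([tree.clone(depth=1) for _ in range(5)])
        assert bp.clade_bipartitions(mcc_tree(sample)) == bp.clade_bipartitions(tree)

    def test_majority_topology_wins(self):
        t1 = "((A:1,B:1):1,(C:1,D:1):1);"
        t2 = "((A:1,C:1):1,(B:1,D:1):1);"
        trees = [parse_newick(t1, rooted=True)] * 2 + [parse_newick(t2, rooted=True)]
        sample = TreeSample([t.clone(depth=1) for t in trees])
        # hand enumeration: {A,B} and {C,D} at 2/3 each, {A,C},{B,D} at 1/3;
        # score(T1) = 2 log(2/3) > score(T2) = 2 log(1/3)
        freqs = clade_frequencies(sample)
        assert freqs[frozenset("AB")] == pytest.approx(2 / 3)
        assert bp.clade_bipartitions(mcc_tree(sample)) == {
            frozenset("AB"),
            frozenset("CD"),
        }

    def test_singleton_sample(self):
        tree = parse_newick("((A:1,B:1):1,C:1);", rooted=True)
        sample = TreeSample([tree])
        assert mcc_tree(sample) is tree


class TestAverageOverTrees:
    def test_identical_trees_equal_single_tree_marginals(self, yule_tree):
        chars, _ = bp.simulate_character(yule_tree, bp.MkModel(2, 0.4), seed=9)
        model = bp.MkModel(2, 0.4)
        sample = TreeSample([yule_tree.clone(depth=1) for _ in range(4)])
        recon = bp.average_over_trees(sample, chars, model=model)
        single = bp.marginal_ancestral(yule_tree, chars, model)
        for clade, summary in recon.per_clade.items():
            assert np.allclose(summary.mean_probs, single[clade], atol=1e-12)
            assert summary.n_trees_used == 4

    def test_clade_in_half_the_trees_averages_over_that_half(self):
        t1 = parse_newick("(((A:1,B:1):1,C:1):1,D:1);", rooted=True)
        t2 = parse_newick("(((A:1,C:1):1,B:1):1,D:1);", rooted=True)
        sample = TreeSample(
            [t1.clone(depth=1), t2.clone(depth=1), t1.clone(depth=1), t2.clone(depth=1)]
        )
        chars = CharacterData(("0", "1"), {"A": 0, "B": 0, "C": 1, "D": 1})
        recon = bp.average_over_trees(sample, chars, model=bp.MkModel(2, 0.3))
        summary = recon.per_clade.get(frozenset("AB"))
        if summary is None:  # MCC tie resolved to t2's topology
            summary = recon.per_clade[frozenset("AC")]
        assert summary.n_trees_used == 2
        assert summary.clade_frequency == pytest.approx(0.5)

    def test_true_root_state_recovered_from_perturbed_sample(self):
        true_tree = bp.simulate_yule_tree(20, seed=31)
        chars, painted = bp.simulate_character(true_tree, bp.MkModel(4, 0.05), root_state=2, seed=32)
        sample = bp.perturb_tree_sample(true_tree, 50, nni_moves=1, length_jitter_sigma=0.05, seed=33)
        recon = bp.average_over_trees(sample, chars, per_tree_alpha=False)
        root = frozenset(chars.assignments)
        assert int(np.argmax(recon.per_clade[root].mean_probs)) == 2
        assert recon.per_clade[root].mean_probs[2] > 0.9


class TestCountTransitions:
    def test_constant_painting_has_zero_transitions(self, yule_tree):
        painted = paint_states(yule_tree, root_state=3)
        recon = painting_to_reconstruction(painted, HABITAT_CLASSES)
        chars = painted_tip_characters(painted, HABITAT_CLASSES)
        summary = count_transitions(recon, chars, modal_threshold=1.0)
        assert summary.counts == {} and summary.unresolved_edges == 0

    def test_single_edge_change_counted(self):
        tree = parse_newick("((A:1,B:1):1,C:1);", rooted=True)
        painted = paint_states(tree, root_state=3, shifts={frozenset({"A"}): 1})
        recon = painting_to_reconstruction(painted, HABITAT_CLASSES)
        chars = painted_tip_characters(painted, HABITAT_CLASSES)
        summary = count_transitions(recon, chars, modal_threshold=1.0)
        assert summary.counts == {(3, 1): 1}

    def test_painted_shift_count_reproduced_exactly(self):
        tree = bp.simulate_yule_tree(20, seed=41)
        clades = sorted(bp.clade_bipartitions(tree), key=len)
        shifts = {clades[0]: 1, clades[1]: 1}
        painted = paint_states(tree, root_state=3, shifts=shifts)
        recon = painting_to_reconstruction(painted, HABITAT_CLASSES)
        chars = painted_tip_characters(painted, HABITAT_CLASSES)
        summary = count_transitions(recon, chars, modal_threshold=1.0)
        assert summary.counts == painted_change_count(painted)
        assert summary.counts[(3, 1)] == 2

    def test_sub_threshold_nodes_counted_unresolved(self):
        tree = parse_newick("((A:1,B:1):1,C:1);", rooted=True)
        chars = CharacterData(tuple(HABITAT_CLASSES), {"A": 1, "B": 3, "C": 3})
        painted = paint_states(tree, root_state=3)
        recon = painting_to_reconstruction(painted, HABITAT_CLASSES)
        flat = {
            clade: bp.ancestral.CladeSummary(np.full(4, 0.25), 1.0, 1)
            for clade in recon.per_clade
        }
        vague = bp.AncestralReconstruction(tree, tuple(HABITAT_CLASSES), flat)
        summary = count_transitions(vague, chars, modal_threshold=0.5)
        assert summary.counts == {}
        assert summary.unresolved_edges == 4  # every edge touches an unresolved node


def test_annotated_tree_carries_probability_comments(yule_tree):
    chars, _ = bp.simulate_character(yule_tree, bp.MkModel(2, 0.4), seed=13)
    sample = TreeSample([yule_tree.clone(depth=1)])
    recon = bp.average_over_trees(sample, chars, model=bp.MkModel(2, 0.4))
    tree = annotate_tree(recon)
    internal = next(tree.preorder_internal_node_iter())
    assert internal.annotations.get_value("state_probs")
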