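"""The synthetic-data generators: trees, alignments, characters, samples.

Each generator is seed-reproducible and mirrors the statistical structure the
analysis assumes: Yule topologies, GTR+I+Gamma sequence evolution, equal-rates
Mk characters with retained true node states, and pseudo-posterior samples.
"""

import numpy as np

import bathyphy as bp
from bathyphy.ancestral import clade_frequencies
from bathyphy.simulate import SubstitutionModel, painted_change_count

tree = bp.simulate_yule_tree(10, birth_rate=1.0, seed=5)
print("Yule tree, 10 tips:")
print(" ", bp.write_newick(tree).strip()[:90], "...\n")

model = SubstitutionModel(
    exchangeabilities=(1.0, 4.0, 1.0, 1.0, 4.0, 1.0),  # transition-biased, HKY-like
    base_frequencies=(0.30, 0.20, 0.20, 0.30),
    p_invariant=0.2,
    gamma_shape=0.5,
)
aln = bp.simulate_alignment(tree, model, length=600, seed=6)
constant = sum(
    1 for i in range(aln.length) if len({s[i] for s in aln.sequences}) == 1
)
print(f"GTR+I+Gamma alignment: {aln.n_taxa} taxa x {aln.length} sites, "
      f"{constant} constant columns")
dm = bp.pairwise_matrix(aln, metric="k2p")
print(f"mean pairwise K2P distance: {np.nanmean(dm.d[np.triu_indices(10, 1)]):.4f}\n")

chars, painted = bp.simulate_character(tree, bp.MkModel(4, 0.2), seed=7)
print("Mk character (k=4, alpha=0.2): tip states", list(chars.assignments.values()))
print("true number of changes on the tree:", sum(painted_change_count(painted).values()), "\n")

sample = bp.perturb_tree_sample(tree, 100, nni_moves=1, length_jitter_sigma=0.1, seed=8)
freqs = clade_frequencies(sample)
true_clades = bp.clade_bipartitions(tree)
mean_true = np.mean([freqs.get(c, 0.0) for c in true_clades])
print(f"pseudo-posterior of 100 trees (1 NNI + length jitter each):")
print(f"  mean frequency of true clades: {mean_true:.2f}")
print(f"  distinct clades observed: {len(freqs)}")
print(
    "\nTrue clades dominate the perturbed sample, so clade-frequency-based\n"
    "summaries (the MCC tree, per-clade averages) behave like they would on a\n"
    "converged Bayesian sample."
)
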