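"""Mk ancestral-state reconstruction of habitat over a tree sample.

Paints a known habitat history on a simulated tree (organic-fall ancestor,
two vent colonizations), reconstructs ancestral states on a pseudo-posterior
sample, summarises them on the maximum clade credibility tree and counts the
directed habitat transitions.
"""

import numpy as np

import bathyphy as bp
from bathyphy.ancestral import count_transitions
from bathyphy.simulate import paint_states, painted_tip_characters
from bathyphy.tables import HABITAT_CLASSES

tree = bp.simulate_yule_tree(16, seed=77)
clades = sorted(bp.clade_bipartitions(tree), key=lambda c: (len(c), sorted(c)))
small = [c for c in clades if len(c) in (2, 3)]
vent_clades = [small[0], next(c for c in small if not (c & small[0]))]

painted = paint_states(tree, root_state=3, shifts={c: 1 for c in vent_clades})
chars = painted_tip_characters(painted, HABITAT_CLASSES)
print("tip habitat states (0=nonchemo, 1=vent, 2=seep, 3=organic fall):")
print(" ", dict(sorted(chars.assignments.items())), "\n")

sample = bp.perturb_tree_sample(tree, 50, nni_moves=1, length_jitter_sigma=0.05, seed=78)
recon = bp.average_over_trees(sample, chars, per_tree_alpha=False)

root = frozenset(chars.assignments)
probs = recon.per_clade[root].mean_probs
print("root state probabilities (averaged over the 50-tree sample):")
for label, p in zip(HABITAT_CLASSES, probs):
    print(f"  {label:<18}{p:.3f}")

summary = count_transitions(recon, chars, modal_threshold=0.5)
print("\ndirected transitions on the MCC tree:")
print(bp.report_transitions(summary, recon))
print(
    "\nThe organic-fall root probability is near 1 and exactly the two painted\n"
    "organic->vent colonizations are counted: the reconstruction recovers the\n"
    "known history despite topological noise in the tree sample."
)
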