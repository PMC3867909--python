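# Methods

This note documents the models, algorithms, parameter choices and known
limitations of bathyphy, in the spirit of the methods documentation of the
established phylogenetics packages.

## Distances and barcode attribution

Pairwise distances use the Kimura 2-parameter correction,
`d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)`, with transitions (A↔G, C↔T) and
transversions counted over the sites where **both** sequences carry an
unambiguous A/C/G/T (*pairwise deletion*). Pairwise rather than complete
deletion is deliberate: barcode reference sets mix GenBank fragments of
unequal coverage, and complete deletion would discard most of the signal.
Every attribution carries the per-pair usable-site count so it can be
audited; pairs with fewer than `min_sites` (default 100) comparable sites
never support an attribution. When a log argument is non-positive the
distance is *saturated*: it is reported as undefined (NaN in matrices), and
no threshold attribution may rest on it.

The attribution procedure is two-step:

1. **Threshold step.** The query is attributed to the closest reference if
   the minimum K2P distance is ≤ the threshold. The default threshold is 2%,
   motivated by reported intraspecific COI distances in deep-sea mussels of
   about 1–1.8%. The boundary is inclusive (d = threshold attributes):
   "within the threshold" is read as attribution-friendly and is documented
   here rather than left ambiguous. Co-minimal references (within 1e-12) are
   all reported; if they span more than one genus the genus field is refused
   and the case marked unresolved. Raising the threshold can only add
   threshold attributions, never remove one (monotonicity, property-tested).
2. **Sister step.** Queries beyond the threshold are placed in a rooted
   tree containing the references — an externally inferred tree if supplied,
   otherwise a neighbor-joining tree over references plus pending queries,
   built from the K2P matrix and midpoint-rooted. (Midpoint rooting matters:
   the NJ algorithm's arbitrary basal join is not a root, and treating it as
   one distorts sister groups for queries attached near it.) The query's
   sister group is inspected; if it contains no reference the search walks
   one level rootward at a time, bounded by the root. At the first
   informative level the genus is assigned iff the reference members agree
   on a single genus. The placement tree is advisory — its topology is used,
   its branch lengths are not — so NJ's negative-branch clamping is
   harmless.

Queries with no usable distance to any reference (no overlap, all pairs
saturated or too short) are passed through as `morphology_only`, mirroring
taxa that can only be placed on shell characters.

## Character coding

- **Habitat** (k = 4): 0 nonchemosynthetic, 1 hydrothermal vent, 2 cold
  seep, 3 organic fall (wood/bone). Free-text habitat fields are parsed
  against a small synonym vocabulary ("wood", "bone", "Intertidal subtidal",
  …). Taxa recorded from several habitat classes are resolved by an explicit
  policy: the default `organic_priority` codes any taxon with an organic
  substrate as 3, else vent, else seep, logging each resolution per taxon;
  `strict` refuses polymorphic taxa. There is no unambiguous convention for
  such taxa, so the choice is a named, logged policy rather than a silent
  guess.
- **Depth** (k = 2): 0 if the shallowest recorded depth is < 1000 m, else 1.
  Exactly 1000 m codes as deep; the cut is conventional and the boundary
  assignment is documented rather than meaningful.

## Mk model, pruning and marginals

The character model is the one-parameter equal-rates Mk process (the model
behind the standard ML reconstruction in Mesquite-style analyses): rate
matrix with α in every off-diagonal cell, closed-form transition matrix
`P_ii = 1/k + (k-1)/k e^(-kαt)`, `P_ij = 1/k - 1/k e^(-kαt)`. Branch lengths
are in expected substitutions per site, α in events per state pair per unit
branch length; only the product αt is identified, so uniformly rescaling a
tree is absorbed into the rate estimate.

Log-likelihoods use Felsenstein's pruning algorithm with a **uniform 1/k
root prior** (the common default for morphological/ecological characters;
the prior is a documented choice, not an inference). Partial likelihoods are
rescaled when they underflow. Taxa present in the tree but missing from the
character are treated as all-states-possible partials. Marginal ancestral
probabilities combine downward (subtree) with upward (rest-of-tree)
partials — algebraically identical to re-rooting at each node — and are
normalised per node; both the likelihood and every marginal vector are
verified against exhaustive enumeration over all interior-node state
assignments on all rooted binary topologies with up to 6 leaves.

**Rate estimation** maximises the pruning likelihood over α ∈ [1e-8, 100]
with a bounded scalar search *on the log scale*, tolerance 1e-6. The log
scale is essential, not cosmetic: the likelihood is flat for large α, and a
linear-scale golden-section search can start on that plateau and never probe
realistic rates. With no variable pattern the likelihood is monotone
decreasing in α; the estimate is pinned to the lower bound with a warning.
Several independent characters may be fitted jointly (summed
log-likelihoods); single-character estimates of α are intrinsically noisy
and occasionally boundary-attracted, which is why the rate-recovery
experiment below uses 10 characters per replicate.

## Tree-sample averaging and transition counting

The summary tree is the **maximum clade credibility** tree: the sample
member maximising the sum over its non-trivial clades of the log of that
clade's frequency in the sample, ties broken by first occurrence. For each
clade of the MCC tree, the marginal vectors of the sample trees *containing
that clade* are arithmetically averaged and renormalised; trees lacking the
clade contribute nothing (not zeros), and the output records both the
clade's sample frequency and `n_trees_used`. The Mk rate is, by default,
re-estimated on every sample tree (each tree has its own branch lengths);
a single shared fit (estimated once on the MCC tree, or supplied) is
available and considerably faster.

Transition counting assigns every internal node its modal state iff the
maximum mean probability reaches `modal_threshold` (default 0.5; leaves use
their observed states), then counts directed (parent → child) state changes
along edges whose two endpoints are both resolved; edges touching an
unresolved node are tallied separately, so "at least N transitions" claims
remain honest. The 0.5 default makes "modal" mean "majority support"; at
threshold 1.0 on a noiseless one-hot painting the counter reproduces the
painted change count exactly (tested).

## Synthetic data

The generators produce data with the statistical structure the analysis
assumes, not facsimiles of any real data set:

- **Yule trees** (pure birth, default rate 1) for topologies.
- **Pseudo-posterior samples**: independent copies of a true tree, each
  after a set number of random NNI moves and log-normal branch-length
  multipliers. This is a stand-in with the right *clade-frequency
  structure* (true clades dominate), not a calibrated posterior; no MCMC is
  run. For scenarios that need a dominant true topology, prepend the true
  tree itself to the perturbed sample.
- **GTR+I+Γ alignments**: root sequence from the stationary frequencies,
  per-site rate multipliers from an invariant/discrete-Gamma mixture
  (4 equal-probability categories by default, category medians renormalised;
  the mixture is scaled so the mean site rate is 1 and branch lengths keep
  their substitutions-per-site meaning), branch transitions by matrix
  exponential of the normalised GTR generator.
- **Mk characters** sampled state-by-state down the tree, returning both tip
  data and the true internal states ("painted" tree) for recovery tests;
  deterministic paintings (`paint_states`) put chosen states on chosen
  clades for transition-counting ground truth.
- **Barcode reference fixture**: sequences evolved on a two-level
  genus/species tree (defaults: 3 genera × 4 species, within-genus K2P 1%,
  between-genus 10%, 660 bp — a COI-scale barcode fragment). Because
  realised K2P only approximates input branch lengths, the tree is rescaled
  empirically (≤3 rounds) until the realised means land within ~20% of the
  requested values; infeasible (saturating) requests are refused. Habitat
  classes cycle across species and depth ranges straddle the 1000 m cut, so
  both encoders are exercised; query tips are conspecific with known
  references and carry truth labels for accuracy scoring.

What passing tests on these data do **not** show: robustness to alignment
error, indels, saturation at real COI depths, base-composition
heterogeneity across taxa, correlated characters, or posterior samples with
real MCMC autocorrelation. The generators are deliberately clean; the tests
certify the inference machinery, not field performance.

## Experiment sizes and numerical choices

Replicated experiments in the test suite and acceptance script use sizes
chosen to give stable statistics at desk scale: 500 replicates (20-leaf
trees, k = 4, rate set for ≈2 expected changes per tree) for root-state
recovery, where the modal root state matches truth in ≥80% of replicates;
200 (tests) / 100 (script) replicates of 10 characters each for rate
recovery, where the mean estimate lands within 20% of the true α = 0.5;
exhaustive topology enumeration up to 6 leaves with 100 branch-length draws
each for the oracle equivalence; NJ recovery on random additive matrices up
to 8 leaves. The acceptance script's habitat scenario paints an
organic-fall ancestor with four vent/seep colonizations and one nested
vent→seep shift on a 32-leaf tree; shifts are placed only on clades whose
stem branch reaches the median branch length, with the seep pair strictly
nested behind an intermediate vent clade and shift clades mutually
separated — a shift painted on a near-zero stem, or two shifts sharing a
tiny neighbourhood, is unidentifiable for *any* reconstruction method, and
demonstrating recovery requires an identifiable truth.

Ties in distances are resolved by reporting, never arbitrarily; MCC ties go
to the first occurrence; NJ negative branch estimates are clamped to zero;
distance matrices flag undefined pairs as NaN instead of raising so one
rogue pair cannot abort a study. All generators and the pipeline are
bit-reproducible for a fixed seed, and the pipeline manifest records the
seed and the decisions in force.

## Limitations

- Asymmetric or ordered-state character models are out of scope (the rate
  interface permits extension); no stochastic character mapping, no
  correlated-character tests, no divergence dating.
- The package never aligns sequences; queries and references must share a
  coordinate frame, guarded only by overlap checks.
- K2P without rate heterogeneity correction underestimates deep distances;
  for genus-level barcode gaps (≈1% vs ≈10%) this is immaterial, which is
  the regime the thresholds target.
- The sister rule inherits whatever placement tree it is given; a poor tree
  yields unresolved (not wrong) attributions by design, but cannot be
  detected internally.
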