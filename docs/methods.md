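# Methods

`phyloscreen` implements a desk-scale phylogenomic congruence screen: given a
partitioned supermatrix, a species tree, gene trees, and discrete character
data, it quantifies (i) how strongly the data violate the stationarity /
reversibility / homogeneity (SRH) assumptions of standard substitution
models, (ii) how decisively quartets of taxa support a phylogenetic
hypothesis, and how much of that support survives once phylogenetic signal is
destroyed, (iii) how gene trees distribute quartet support around each
species-tree internode, and (iv) the history of discrete (e.g. larval
ecology) characters on a fixed tree. A synthetic-data generator provides all
inputs with the statistical pathologies these analyses are designed to
detect.

## Supermatrix diagnostics

**Bowker's test of symmetry.** For a taxon pair (i, j), the divergence table
N counts sites with state a in i and state b in j, over sites where both
taxa are non-missing (pairwise deletion). The statistic is

    B = sum_{a<b} (N_ab - N_ba)^2 / (N_ab + N_ba),

summed over unordered state pairs with N_ab + N_ba > 0; the degrees of
freedom equal the number of such pairs, and p is the upper chi-square tail.
Under SRH evolution E[N] is symmetric, so rejection flags model violations.
Conventions: df = 0 (e.g. identical sequences) yields p = 1 so that medians
over pairs stay defined; a pair with zero comparable sites is reported as
undefined and excluded from the median. IUPAC partial ambiguity codes are
treated as missing (configurable).

**RCFV.** For one partition, with A_sj the relative frequency of state s
among taxon j's observed characters and Ā_s the mean over the n taxa that
have any data there,

    RCFV = sum_s sum_j |A_sj - Ā_s| / n.

Per-taxon frequencies are computed over observed characters only, so
missingness is not conflated with composition. Masking removes partitions
with RCFV ≥ 0.1 (inclusive). Note that RCFV has a sampling-noise floor that
scales like k/sqrt(L) for alphabet size k and partition length L: for 20
amino-acid states the floor crosses 0.1 only near L ≈ 1000, so the default
threshold is meaningful for partitions of roughly that length and above;
shorter partitions need a rescaled threshold (the bundled demo uses 800-site
partitions, where shifted and clean partitions separate cleanly at 0.1).

**Completeness.** C_a is the fraction of non-ambiguous cells overall; the
per-taxon and pairwise variants are defined analogously (a pair's score is
the fraction of columns where both taxa are unambiguous).

**Decisive filter.** A partition survives when every taxon has at least one
observed character in it, its ambiguous-cell fraction is strictly below 0.30,
and it spans at least 500 sites. "Strictly below" vs the inclusive length
bound follows the wording of the rules as commonly stated; both boundaries
are covered by tests.

## Likelihood engine

Time-reversible models are built as Q = S·diag(π) from a symmetric
exchangeability matrix S and frequencies π, rescaled to one expected
substitution per unit branch length. Transition matrices use the symmetric
eigendecomposition of diag(π)^{1/2} Q diag(π)^{-1/2}, which is stable for
reversible generators; tiny negative entries from round-off are clipped and
rows renormalized. Among-site rate variation is the discrete-gamma mixture
with equal-probability categories and category means (4 categories by
default), renormalized so the mean multiplier is exactly 1. Felsenstein
pruning runs on unique site patterns with per-node scaling; missing states
contribute all-ones partial likelihoods, so an all-missing column has
log-likelihood 0. The built-in models are dependency-free (poisson/JC
exchangeabilities, empirical or uniform frequencies); empirical amino-acid
matrices can be loaded from PAML-format `.dat` files. Equilibrium
frequencies default to empirical counts with a pseudocount of 1 per state,
which keeps frequencies positive on four-row quartet sub-alignments.

## Four-cluster likelihood mapping (FcLM)

A hypothesis is four disjoint taxon groups. Quartets take one taxon per
group; the full Cartesian product is used when it is at most the cap
(default 20,000), otherwise a seeded uniform sample without replacement.
Each quartet keeps only columns where all four taxa are observed
(complete deletion, logged per quartet because it interacts with
missing-data permutations) and is skipped below 30 usable sites. For each of
the three unrooted topologies the five branch lengths are optimized with
bounded L-BFGS in log-space (domain 1e-8..10, ftol 1e-6, 3 restarts; the
restart starting points are symmetric in the four terminal branches and
seeded per quartet from a hash of its sorted taxon names, which makes
results exactly invariant under relabeling the groups). Support weights are
the softmax of the three optimized log-likelihoods.

The simplex is partitioned by nearest prototype: corners (1,0,0)…, edge
midpoints (½,½,0)…, and the center (⅓,⅓,⅓), with ties broken in a fixed
order. This is a convex, easily testable approximation of the classic
likelihood-mapping regions; the exact historical boundaries differ slightly,
and the rule is isolated behind `assign_region` so it can be swapped. Two
summaries are reported: 7-region occupancy percentages (summing to 100 over
evaluated quartets), and topology-support percentages renormalized over the
three corner regions — the headline "% of quartets supporting topology i".
The renormalized form is what makes a signal-free matrix read as ~33/33/33
even when few quartets sit exactly in the center region.

The default model for a hypothesis run is poisson exchangeabilities +
alignment-wide empirical frequencies + gamma(4); the shape is either given
or profiled once on a random 50-quartet subsample (coarse-then-fine grid on
the T1 topology) and then fixed, so all quartets are scored under one model.

## Signal-destroying permutations

Three schemes, all per-partition, all preserving shape, taxon order,
partition scheme and the missing-data mask bit-for-bit, all deterministic
given a seed:

* **columnwise** — each column's observed residues are shuffled among the
  taxa covered in that column. Preserves per-column state multisets (hence
  the site-rate profile); destroys tree signal and lineage-specific
  composition. This is the "signal eliminated" permutation used as the FcLM
  null.
* **rowwise** — each taxon's observed residues are shuffled across its own
  covered sites. Preserves per-taxon per-partition composition (hence the
  SRH-violation structure); destroys shared site patterns.
* **mask-only** — observed cells are redrawn i.i.d. from pooled partition
  frequencies. Preserves only the coverage pattern.

The published permutation schemes these correspond to are defined in
supplementary material not reproduced here; the schemes are therefore
specified by their preserve/destroy contracts, which are what the tests
verify.

## Gene-tree quartet support

Each internal edge of the binary unrooted species tree defines a
quadripartition A|B|C|D (the four leaf sets incident to the edge's
endpoints; polytomies are skipped with a warning). Up to 1000 quartets per
edge (one leaf per part; full enumeration when possible) are classified in
every gene tree by split containment: arrangement 1 agrees with the species
tree, 2 and 3 are the alternatives, a polytomy is unresolved, and a missing
taxon makes the observation missing. q_i is the count share among resolved
observations; unresolved observations are excluded from the denominator and
raw counts are reported alongside. This is a scoring re-implementation of
per-internode quartet support — no species-tree search is performed, and the
sampled tally is an estimator of, not a byte-level replica of, any
particular coalescent program's annotation.

## Discrete-character mapping

**Sankoff parsimony** with arbitrary cost matrices (unit costs by default);
missing tips allow every state. The backtracking pass records, per node, the
union of states over all most-parsimonious reconstructions; a branch enters
the apomorphy list only when parent and child sets are disjoint singletons,
i.e. every MPR implies the same change. Unit-cost results are cross-checked
against an independent Fitch implementation.

**Mk maximum likelihood.** ER (1 rate), SYM (k(k-1)/2) and ARD (k(k-1))
generators with uniform root prior by default (configurable); rates are
optimized in log-space (bounds 1e-9..1e3) with multiple starting points
scaled by total tree length. Branch lengths may be in time units; the rate
absorbs the scale. Model selection fits the three structures in nesting
order, seeding each from the previous optimum so fitted log-likelihoods
respect ER ≤ SYM ≤ ARD by construction; both AIC and AICc are reported. An
MLE pinned at the bounds (constant characters) is flagged.

**Stochastic character mapping.** Node states are sampled jointly — the root
from its exact posterior, then children pre-order from
P(child | parent, tips below) — using the inside pass of the exact
inside-outside recursion, so node-state frequencies are unbiased estimates
of the marginal posteriors (the exact marginals are computed by the same
recursion and serve as the oracle in tests). Branch substitution paths are
then sampled conditional on their endpoints: forward simulation with
rejection first, and a uniformization bridge (conditional jump-count
sampling with the uniformized chain) after 1000 failed attempts per
endpoint group; fallback usage is logged. Summaries over histories: node
posterior frequencies, per-branch expected transition counts by ordered
state pair, and expected dwell time per state (their sum equals total tree
length exactly, since paths tile every branch).

## Synthetic data

The generator owns the study conditions. Defaults: 20 taxa on a Yule tree
rescaled to 0.5 expected substitutions per site root-to-tip; four 300-site
amino-acid partitions under a poisson model with gamma(α = 1, 4 categories)
rates; compositional shifts implemented as a frequency switch (same
exchangeabilities, perturbed π) on every branch whose descendant leaves all
belong to a designated taxon set — the simplest non-stationarity a symmetry
test should detect; block-wise taxon-by-partition occupancy plus optional
per-site dropout, applied after simulation by overwriting cells with `-`;
gene trees equal to the species tree or (probability ε = 0.2) a uniformly
chosen NNI neighbor; and binary Mk characters at ER rate 0.5. The canonical
shift target concentrates 90% of frequency mass on a quarter of the states
(a GC-rich-like bias), applied at weight 1.0 on lineages diverging ~2
substitutions/site in the power scenarios — shifts of that order are needed
for unambiguous detection at 10^3-site scale and are within what deep
phylogenomic datasets show for strongly biased lineages. All randomness
derives from one master seed through named substreams, so outputs are
byte-reproducible.

What the generator does *not* emulate: alignment/orthology errors,
coalescent (rather than NNI) discordance, covarion-style heterogeneity,
indel processes, or codon structure beyond frame bookkeeping. Passing tests
therefore demonstrate correctness of the statistics and the direction of
their response to the modeled pathologies, not performance on real
transcriptomic supermatrices.

## Problem sizes used in checks

The bundled checks run at desk scale, chosen so the whole battery completes
in minutes on one core: likelihood-mapping recovery uses 20 taxa, 300 sites
and 200 quartets; the permutation null averages corner shares over five
columnwise permutation replicates of that matrix (quartets on a single
permuted matrix are correlated through shared columns and taxa, so one
replicate's shares scatter far more than independent-quartet binomial error
suggests — the mean over replicates estimates the uniformity that holds in
expectation); symmetry-test calibration uses 540 null pairs of 1000 sites;
rate recovery uses 200 characters on 100 taxa; stochastic mapping uses
10,000 histories on 10 taxa; the demo pipeline uses 12 taxa with three
800-site partitions. Real supermatrices (10^5–10^6 sites) make the same
statistics far better resolved; the caps (quartets per hypothesis, quartets
per edge) exist so the estimators remain well-defined at any scale.

## Known limitations

* The simplex-region boundaries are a nearest-prototype approximation, not
  the exact classical construction; percentages near region borders can
  differ from other implementations.
* Per-edge quartet support is a sampled estimator; it shares semantics, not
  normalization details, with full weighted-tally implementations.
* FcLM uses one shared model per hypothesis rather than per-partition
  models.
* The Mk root prior is uniform by default; stationary-distribution or
  fitted priors are available only through the `root_prior` argument.
* Branch-length optimization is bounded to [1e-8, 10] substitutions/site;
  saturated quartets pile up at the bound rather than diverging.
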