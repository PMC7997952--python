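# Methods

This note documents the models and procedures implemented in
`ancestornet`, the defaults chosen where the design was genuinely open,
and what the synthetic-data tests do and do not establish.

## Genome selection and grouping

A genome is classified aerobic when it carries at least one homolog of
the heme-copper oxygen reductase / NO reductase reference set with
identity strictly greater than 25 %, E-value strictly below 1e−10 and
an alignment of at least 300 residues; all three thresholds are applied
literally and are configurable. Anaerobes with more than 1000 proteins
are retained — the protein-count floor excludes obligate energy
parasites whose extreme gene loss would distort universality counts.

Taxonomic groups are phyla, except that Firmicutes and Proteobacteria
are split into classes (their representation is an order of magnitude
larger than other phyla) and phyla with fewer than five species are
pooled into a residual "Other Bacteria" bin. "Species" means distinct
binomial names in the metadata, the only species-level information
available.

## Protein families (MCL)

The similarity graph keeps edges with global identity ≥ 25 % *and*
E ≤ 1e−10 (note the inclusive senses, deliberately different from the
strict oxygen-classification thresholds); edge weight is the identity,
duplicates collapse to the maximum. Markov clustering uses inflation
2.0 — the standard MCL default, configurable — with self-loops set to
each node's maximum incident weight before column normalisation, the
usual stabilisation. Iteration alternates expansion (matrix squaring)
and inflation (entrywise power, column renormalisation) until the
matrix changes by less than 1e−6 (max-norm) or 200 iterations; values
below 1e−12 are pruned to keep the converged matrix sparse in effect.
Clusters are connected components of the converged attractor structure,
which makes the partition independent of node labelling; family ids are
assigned by decreasing size with lexicographic tie-break, so results
are fully deterministic. Non-convergence returns the current partition
with a warning marker rather than failing.

Family filtering requires ≥ 3 species and ≥ 4 genomes. Universal
families are those present (≥ 1 genome) in every group. Mean coverage
averages the per-group presence *fractions* with equal group weight
(not pooling genomes, which would let the largest groups dominate);
this is the reading used for the "present on average in ≥ 90 % of a
group's genomes" summary.

Functional annotation keeps, per sequence, the best hit passing query
coverage ≥ 0.8, E ≤ 1e−10 and length ratio in [0.7, 1.3]; best means
lowest E-value, ties broken by higher coverage, then higher identity,
then subject id (the last purely for determinism). The family label is
the most frequent category among annotated members; frequency ties keep
all tied categories.

## Reactions and the bipartite network

Equations follow the KEGG dialect `a C1 + b C2 <=> c C3` (coefficients
optional, `=>` for directed). Rejected at parse time: symbolic
coefficients (`n`, `m`, `n+1`, `2n`…), malformed compound tokens, and
— by default, overridable — compounds appearing on both sides
(transport/polymer-growth cases, which are not meaningful in a
producibility analysis). Reversibility comes from a separate table;
absent reactions default to irreversible. A reversible reaction is one
object with a flag, not two directed copies, keeping ids stable.

The bipartite graph has substrate→reaction and reaction→product edges,
both orientations for reversible reactions. Components and degrees are
reported on the undirected skeleton, since connectivity claims about
such networks are undirected. A reaction's distribution score is the
number of taxonomic groups where at least one encoding family occurs —
monotone in the family set by construction.

## Scope and greedy reduction

Scope (network expansion) is the least fixed point of firing reactions
whose substrate side — either side, if reversible — is contained in
the current compound set. The implementation retires satisfied rules
from the worklist; tests verify equality with a naive rescan-everything
oracle, order independence, monotonicity in seeds and reactions, and
idempotence.

Target producibility has two modes. The default, `produced_by_any`,
calls a target producible when some reaction yields it as a product
(either side if reversible); this matches an analysis in which the core
network is not expected to be self-generating from nutrients.
`scope_from_seeds` demands the target lie in the scope of a seed set;
the default seed set is the compounds that appear only as substrates
(external inputs), configurable, since no canonical seed set exists for
a reconstructed ancestral network.

The reduction visits candidates in increasing distribution score (ties
by reaction id, for determinism), removes each temporarily, and makes
the removal permanent iff all targets remain producible; full passes
repeat until a pass removes nothing — the stopping rule "no further
reaction can be removed" requires this re-checking. Core reactions are
never candidates; "core not violated" is implemented as "all core
reactions retained". The result is checked 1-minimal after the fact:
removing any single retained candidate breaks a target. Global
minimum-cardinality search is NP-hard and deliberately out of scope;
the exhaustive subset oracle appears only in tests (≤ 15 candidates),
where the greedy result equals the exhaustive optimum whenever that
optimum is unique.

## MAD rooting

For a candidate root ρ, each leaf pair's induced ancestor is the
Steiner point of (b, c, ρ), giving the pairwise relative deviation
|2·d(b,anc)/d(b,c) − 1| = |d(b,ρ) − d(c,ρ)| / d(b,c). Per branch, the
cross-pair contribution is quadratic in the root position, so the
minimiser is closed-form and clamped to the branch; same-side pairs
contribute constants. The branch score is the root-mean-square over
all pairs; branches are ranked and the ambiguity index is best/second
MAD. A tree is ambiguous when the second branch matches the minimum
within relative tolerance 1e−6 (configurable); ambiguous trees are
dropped from all downstream analyses.

Numerical choices: a bifurcating input root is collapsed first, so the
result is invariant to the arbitrary rooting of the Newick
representation; zero-length pair distances are skipped in the deviation
(denominator guard) and logged; an all-zero-length tree is an error; a
zero-length branch puts the nominal root position at 0.5. Internal
labels and support values in Newick are ignored; multifurcations are
treated as hard polytomies (root positions only on existing branches).

## Divergence, sister diversity, root states

Root-to-tip distance is either the branch-length sum (phenetic) or the
node depth — the number of branching events, i.e. edges, on the
root-to-leaf path, so the root's initial split contributes one. Both
are normalised per tree by the largest distance, bounding values to
(0, 1] with at least one exact 1; branch-length normalisation is
scale-invariant. Each group is represented per tree by its *least*
divergent genome; across-tree means average only the trees where the
group occurs.

Pure clades of a group are maximal subtrees whose leaves all carry the
group's label; each clade's sister is the union of the other children
of its parent (for a child of the root: the rest of the tree). The
sister-diversity score is the maximum over pure clades of the number of
*other* distinct group labels in the sister — the focal group is
excluded, which bounds the score to [1, G−1] (the sister of a maximal
pure clade always contains at least one other group). A tree that is
entirely one group yields no record.

Root states use the F81 model: P(i→j, t) = π_j + (δ_ij − π_j)·e^(−βt)
with β = 1/(1 − Σπ²), a post-order pruning recursion (per-node
rescaling against underflow), and root posterior ∝ π × conditional
likelihood. Frequencies default to empirical pooled tip frequencies;
uniform or user-supplied frequencies are accepted. The prediction is
the maximum-posterior state; states within a factor of two of the
maximum are co-reported. This is a deliberate approximation of
marginal-posterior state-set selection: the across-tree aggregation
uses only the single prediction, so the exact set-selection rule would
not change the aggregate. Across trees, predicted root states are
tallied and the modal state (ties reported as ties) is the inferred
ancestral state.

Verticality (0–24, higher = more vertically inherited) is consumed as
a per-family table; a reaction's verticality is the unweighted mean
over its encoding families that have entries, with missing entries
logged and a fully unscored reaction flagged undefined.

## Statistics

The one-sided paired Wilcoxon signed-rank test (H1: the first group is
less divergent) drops zero differences (Wilcoxon's convention), uses
midranks for ties, and computes the exact null by dynamic programming
over doubled midranks for up to 12 effective pairs — equivalent to
enumerating all 2^n sign assignments, and valid under ties — switching
to the tie-corrected, continuity-corrected normal approximation above
that. The two branches agree within 0.01 at the cutoff. The exact test
is conservative at small n because of discreteness; null calibration
checks therefore use n where the normal branch applies. All group
pairs are tested in both directions (the matrix is asymmetric);
Bonferroni multiplies by the number of tested pairs. Pairs with no
shared trees are reported as missing, never silently dropped. In an
analysis with a residual "Other Bacteria" bin, that bin is typically
excluded from the pair matrix (C(24,2) = 276 pairs for 24 proper
groups); the group list is caller-controlled.

The KS comparison wraps the asymptotic two-sample test (ECDF supremum
statistic, Kolmogorov distribution with effective size
n_x·n_y/(n_x+n_y)); tests pin it to a brute-force ECDF oracle.

## Synthetic data: what it emulates and what it does not

The species history is a pure-birth ultrametric tree of height 1 with
the basal group grafted directly at the root behind a stem of 0.3 —
this makes "earliest-diverging" an unambiguous planted truth. Gene
trees restrict the history to non-lost genomes (i.i.d. loss per
genome), apply a Poisson(lgt_rate × branch count) number of
prune-regraft transfers (topology-level moves; the transferred lineage
keeps its own branch lengths and attaches at the recipient branch's
midpoint), and multiply branch lengths by i.i.d. lognormal(0, σ) rate
noise. Defaults for the recovery experiments: 8 groups × 2 genomes,
lgt_rate 0, loss 0, σ = 0.2 — enough noise that rooting is non-trivial
but the planted signal is recoverable; discrete traits evolve down the
history at switch rate 0.05 per unit length, low enough that the root
state is recoverable from tips. Generators are pure functions of
(parameters, seed).

Planted reaction universes build a core chain from one external seed
compound; each planted candidate is the *only* producer of one
remaining target, and decoys only interconvert byproducts, so the
planted set is provably the unique minimum. Planted similarity graphs
draw within-cluster identities ~N(60, 5) and between-cluster ~N(15, 5)
with edge probabilities 0.9/0.05 and E-values consistent with the
25 %/1e−10 thresholds. In the acceptance run the background presence
profile for the universality stage is sparse (p = 0.1 per genome) so
that chance universality is rare, as it is in real family tables.

These generators emulate the *statistical structure* the analyses
exploit — discordance from transfer, rate noise, planted minimal sets
— not real data: there is no sequence evolution, no alignment or
tree-estimation error, no correlation between a family's function and
its verticality, and group sizes are balanced. Passing recovery tests
therefore shows the inference machinery is correct and well-calibrated
under its own model, not that real gene trees satisfy that model.

## Problem sizes and known limitations

Test and acceptance runs use desk-scale sizes chosen to exercise every
code path with tight oracles: 8-taxon trees against a 1000-position
grid-search rooting oracle, 20-reaction networks against a brute-force
fixed point, ≤ 15 candidates against exhaustive subset search, 100
replicates of 100–200 gene trees for recovery rates, 10,000 replicates
for test calibration. The MAD implementation is O(branches × leaf
pairs) per tree with vectorised per-branch arithmetic; it is routinely
used on hundreds of leaves.

Known limitations: MCL on dense matrices is quadratic in node count
per iteration, fine for tens of thousands of sequences per connected
component but not millions; the exact set-selection rule of marginal
posterior approximation is simplified as described; rate heterogeneity
across sites/states, alignment and tree inference, and flux-level
network modelling are out of scope.
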