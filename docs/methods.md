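# Methods

## Normalization

For gene *i* in one library, TPM is
TPMᵢ = 10⁶ · (θᵢ/ℓᵢ) / Σⱼ(θⱼ/ℓⱼ), with θ the mapped-read count and ℓ the
effective length; columns sum to 10⁶ and average 10⁶/*n* for a reference of
*n* genes. TPM10Kᵢ = TPMᵢ·n/10⁴ fixes the per-library mean at 100 for every
species. *n* is the full reference gene count supplied per species in
configuration, not inferred from the (filtered) matrix: gene filtering
(rRNA out, protein-coding only, count > 0 in ≥ 2 libraries) is applied to
the analysis set, while the normalizing constant describes the reference.

Replicates of one (species, tissue) are averaged on the linear TPM10K scale
and then log-transformed with a configurable pseudocount (natural log by
default; base is configurable because nothing downstream depends on it —
scaled changes and the ±2 band simply inherit the unit).

**Pseudocount.** The default is 1 for plain log summaries. Ratio analyses
use pseudocount 0 (zero means drop with a warning): the counting-efficiency
argument — an unknown per-(gene, species) factor e cancels in
log(e·x₁) − log(e·x₂) — is exact only on the pure log scale, whereas
log(e·x+1) distorts small values gene- and species-wise and can manufacture
apparent branch changes where there are none.

**Counting efficiency and ratios.** Expected counts are modelled as
e(gene, species) · x(gene, library) · length. Within-species tissue ratios
cancel e at the gene level. One caveat is inherent to relative measures:
changing one gene's efficiency also perturbs each library's TPM normalizing
sum, which shifts *every* gene's log-ratio by a constant shared across
genes for that library pair. Gene-relative (centred) log-ratios are
therefore exactly invariant in all cases; raw log-ratios are exactly
invariant whenever tissue composition is proportional (multiplicative
tissue effects — e.g. the σ² = 0 scenario), and invariant up to that common
depth-like constant otherwise. The tests assert both forms.

## Gene-tree annotation

Events follow the species-overlap rule: an internal node is a duplication
iff the species sets of its child subtrees intersect, else a speciation.
Pre-existing NHX `Ev` tags are honoured per node so upstream
reconciliations can be consumed unchanged. Speciation nodes map to the MRCA
of their descendant species in the species tree. Walking root→tips, a
speciation node whose mapping already occurred at a non-null speciation
ancestor is demoted to null (mapping retained for diagnostics); duplication
nodes on the path do not reset the scan, since the point of null-marking is
to avoid equal-age calibration constraints on nested nodes and an
intervening duplication does not relieve that conflict. Nonbinary gene-tree
nodes are tolerated defensively (one event over all children).

## Tree filters

Defaults, all configurable, all strict inequalities:

| stage | rule | default |
|---|---|---|
| pre-calibration | max branch length | > 2 discards |
| pre-calibration | fraction of branches at the default length 10⁻⁶ | > 0.25 discards |
| pre-calibration | null nodes per internal node | > 0.3 discards |
| pre-calibration | speciation events | < 1 discards |
| post-calibration | root age (species root = 1) | > 5 discards |
| post-pruning | tips with expression values | < 3 discards |

The long-branch and default-fraction rules combine as OR (either pathology
suffices — both are independent signs of an unreliable tree); AND is
available. Branch statistics exclude the root edge, which has no meaning on
a rooted Newick tree. Filters are monotone in their thresholds and
order-independent across trees.

## Time calibration

Non-null speciation nodes are pinned exactly to their species-tree node
ages; tips to age 0. Unconstrained nodes (duplications, nulls) are placed
between their nearest constrained ancestor and their oldest constrained
descendant, proportionally to the original substitutions/site lengths along
the path; if every length on the path is at or below the default 10⁻⁶,
ages are spread evenly instead, which avoids zero-length calibrated
branches. Processed top-down this reproduces global proportional placement
along chains while guaranteeing strict parent-over-child ordering. An
unconstrained region containing the root is aged bottom-up, each node
placed above its oldest child by that child's branch length converted at
the child subtree's local substitution rate (mean tip distance / child
age). Calibration fails — reporting the offending node pair — exactly when
the constraints themselves violate ancestor/descendant ordering.

This deterministic interpolation replaces penalized-likelihood dating: it
is reproducible, dependency-free, idempotent, and shares the contract any
PL method must satisfy (constrained ages exact, strict ordering). A PL
optimizer can be plugged in behind the same interface; numeric equality
with any particular smoothing objective is not claimed.

## Ancestral reconstruction

Trees are pruned per tissue to tips with observations; suppressed degree-2
nodes have their incident time lengths summed (pairwise tip distances are
conserved) and surviving nodes keep their identities. Joint ML ancestral
states under Brownian motion minimize Σ_branches (Δvalue)²/t, solved
exactly by a two-pass pruning algorithm (upward precision-weighted means,
downward combination with the parent); branch lengths are floored at 10⁻⁹
so precisions stay finite. Values are mapped back onto the unpruned tree;
suppressed nodes stay valueless (provenance `absent`) — interpolating them
would invent data. Tissues are reconstructed independently; ratio traits
are endpoint differences of two tissues' reconstructions, defined only at
nodes valued for both.

Properties that follow (and are tested): reconstructed values lie within
the tip-value range, are invariant to global branch-length rescaling, and
are affine-equivariant in the tip values.

## Branch changes and species-equivalent branches

Scaled change = (child − parent)/branch time on every branch with both
endpoints valued; branch times below 10⁻⁹ are floored and the record
flagged. Classification: negative < −2, positive > 2, neutral on the closed
band in between (band edges neutral; the large-change report uses
|change| > 5). A branch u→v is species-equivalent to the species branch
above node s iff u is a non-null speciation node and v is a non-null
speciation node (or a tip) with mapping s and parent-of-s = mapping of u.
Tip branches are eligible — terminal species branches receive them.
Tallies count (species branch × tissue × class); the per-branch mean over
tissues summarizes sampling breadth.

## STF and variance partitioning

Strict orthologs require exactly one tip per listed species in the family
and a speciation-only connecting subtree; an ancestrally duplicated family
is excluded even when each copy is species-complete, because its lineages
are not related only by speciation. Expression grids (species × tissue,
complete cases only, replicate means, linear TPM10K) are decomposed with an
additive two-factor OLS model via statsmodels; each factor's share is its
type-II (order-invariant) sum of squares over the total. Sequential sums of
squares would make results depend on factor order for unbalanced data; on
the balanced complete-case grids used here all conventions coincide.
SVG/TVG labels use the > 75% combined-variance and 2× dominance rules.

## Simulator

The generator defines the study conditions used throughout the tests:

- species tree: deterministic 7-species ladder, ultrametric, root age 1,
  evenly spaced splits (branch labels A–L as in a preorder lettering);
- gene trees: birth–death inside the species tree, duplication 0.3 and
  loss 0.2 per unit time (moderate turnover: a few duplicated tips per
  family, occasional losses), true events and ages retained on every
  surviving node; substitution lengths are the time lengths times a
  unit-mean gamma factor (shape 3) emulating rate variation;
- expression: per (tree, tissue) an independent BM of log-expression along
  the true time tree, σ² = 0.25 by default, root log-TPM10K 3.0, tissue
  offsets N(0, 0.5²);
- libraries: 5 tissues × 3 replicates per species, log-normal replicate
  noise (sd 0.05), log-normal counting efficiencies (sd 1.0), multinomial
  sequencing at 10⁶ reads per library (multinomial rather than Poisson so
  library size is conserved exactly).

What it deliberately does not emulate: assembly/mapping artifacts,
correlated efficiencies, within-species DGE structure, unbalanced designs,
or expression-dependent loss. Passing tests therefore demonstrate the
pipeline's internal correctness and its invariances, not robustness to
those real-data pathologies.

`empirical_bm_params` (root = tip mean, σ² = tip variance / mean depth) is
a moment-matching convention for seeding simulations from data, not an ML
estimator.

## Problem sizes and numerical conventions

Test and acceptance runs use desk-scale sizes chosen to make the checked
properties sharp: 1,000 random libraries for the normalization identities,
50 trees (≤ 8 tips) against the brute-force ASR oracle at 10⁻⁶, 200
duplication–loss trees for the event-label oracle, 200-family σ² = 0 studies
for end-to-end neutrality (small references make the TPM normalizing
sums noisy mixtures over families, so neutrality needs a realistically
sized reference; see the counting-efficiency caveat above), 500 multinomial simulations for efficiency
cancellation, 1,000 planted genes for SVG/TVG recovery (4 species × 4
tissues, effect sd 1, noise sd 0.1), and 10,000 replicates for the BM
moment checks. Tolerances: ultrametricity 10⁻⁸ of root age; constrained
calibration ages exact; age ordering gap 10⁻¹²; ASR branch floor 10⁻⁹;
change-denominator floor 10⁻⁹ (flagged).

## Known limitations

- Calibration is interpolation-based; absolute node ages for duplication
  nodes depend on the (noisy) substitution lengths along the path.
- The root-side unconstrained region uses a local-rate heuristic; deep
  duplication ages above all constraints are order-of-magnitude placements
  (the root-depth filter exists precisely to catch the pathological ones).
- Raw (non-ratio) scaled changes confound counting efficiency with real
  expression change across species; the ratio channel is the supported
  cross-species readout.
- No uncertainty is attached to ancestral states or branch changes; the
  ±2 band is a descriptive convention, not a significance threshold.
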