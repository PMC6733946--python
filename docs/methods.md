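# Methods

This note records the models, conventions and numerical choices behind
each module, the open design points and how they were resolved, and
what the synthetic-data conditions do and do not establish about real
data.

## Species tree and branch classes

The species tree is consumed, never inferred: a rooted Newick string
with branch lengths in expected substitutions per site. Internal labels
on the *species* tree are node identifiers; internal labels on *gene*
trees are branch supports in [0, 1]. This split matches how the two
file kinds are produced in practice (annotated backbone trees vs. ML
gene trees with SH-like supports). A missing branch length defaults to
1.0 with a loud warning, keeping rate computations defined; a basal
multifurcation is rejected unless the caller asserts the rooting,
because Newick does not distinguish rooted from unrooted trees.

Every branch (identified by its child node) receives exactly one class:
`ORIGIN` for branches subtending the user-designated trait-origin (BCZ)
nodes, `EXCLUDED` for the outgroup clade including its stem,
`TERMINAL` for leaf branches, `PRE_ORIGIN` for in-group internal
branches ancestral to an origin node, `POST_ORIGIN` for the rest.
Whether "pre-origin" should cover anything beyond the root-to-origin
backbone is genuinely open; this package limits it to proper ancestors
of origin nodes, which keeps the three rate classes disjoint and
interpretable. The root itself subtends no branch; events mapped to the
species root are bookkept on an implicit root stem that carries no
length and never enters rate calculations.

## Reconciliation

Gene trees are reconciled by LCA mapping: each gene node maps to the
species MRCA of its leaf species; a node is a duplication iff it maps
to the same species node as one of its children. For a gene edge with
parent mapped to S and child to C at species-path distance d, the
implied losses are d − 1, plus one when the parent is a duplication and
C ≠ S; each loss is placed on the off-path sibling branch at the
skipped species node — the unique placement under which replaying
events down the tree reproduces every extant copy count (this replay is
asserted for every family the package processes).

Before reconciliation, internal edges with support below the threshold
(default 0.9, appropriate for SH-like supports, which run less
conservative than bootstrap) are contracted; a missing support means
full support and is never collapsed, because silently contracting
unannotated edges would destroy resolved topology. The resulting
polytomies are re-resolved greedily: among the current children of a
polytomy, join the pair whose combined species set has the deepest MRCA
(deferring coalescence defers duplications), breaking ties
lexicographically on each subtree's smallest leaf label. This is a
deterministic stand-in for a full duplication-loss rearrangement
search; it is exact on the simulated families tested but is not claimed
to reproduce any particular rearrangement tool's output. Gene trees are
consumed as rooted; no re-rooting search is performed.

## Dollo mapping and copy numbers

Under Dollo parsimony a family is gained once — at the MRCA of the
species that retain it — and thereafter only lost. The gain is recorded
on the branch subtending the origin node, so the origin node itself has
copy number ≥ 1. Losses forced by the presence pattern are one per
maximal retained-free clade below the origin, which is the single-gain
minimum (verified against exhaustive search in the tests). For families
with a reconciled gene tree, duplications and losses come from the
reconciliation (whose losses subsume the Dollo set); presence-only
families take Dollo losses and book k − 1 terminal duplications for a
species observed with k copies — terminal events never enter the
screen, so this convention only preserves copy conservation. Families
are mapped whole; decomposing families into orthogroups before mapping
is a separate, underspecified step that this package deliberately does
not guess at.

Ancestral copy numbers are the running sum of gain + duplications −
losses along each root path; any negative intermediate is a hard error
naming the family, since it means the event map is inconsistent.

## Threshold-model ancestral states

The binary trait is the sign of a latent liability evolving by Brownian
motion. Because the liability scale of a binary trait is
unidentifiable, the diffusion rate is fixed at 1 and the threshold at
0. Tip liabilities are constrained to the half-line of the observed
state; tips coded uncertain are unconstrained. All liabilities are
updated by exact Gibbs draws: a node's full conditional given its
neighbours is normal with precision Σ 1/tᵢ over incident branches, and
constrained tips draw from the one-sided truncated normal given their
parent (inverse-CDF sampling, switching to exponential-rejection
sampling beyond five standard deviations, where the inverse CDF loses
accuracy). PP at a node is the fraction of post-burn-in sweeps with
positive liability; burn-in defaults to 20% of generations, and 100,000
generations is the desk-scale default (posterior summaries on the small
trees in the test suite are stable to ±0.02 at that length, matching a
grid-quadrature oracle).

The root carries an improper flat prior by default, realised through
its Gibbs conditional on its children — the choice that follows the
Brownian pruning algebra without inventing a proper prior. Two
consequences are worth knowing. First, if every constrained tip carries
the same state the posterior is improper (the likelihood does not decay
in one direction) and the chain will drift; PPs for such monomorphic
data are not meaningful. Second, calibration against forward
simulations is only well-posed when the inference prior matches the
generative one, so `ancthresh_mcmc` accepts an optional proper Gaussian
`root_prior`; the reliability check in the test suite draws the true
root liability from N(0, 1) and hands the sampler that same prior.
Posterior probabilities for the three origin nodes are treated
qualitatively (they should rise monotonically towards the crown), not
as hard numeric targets: the PP scale depends on root-prior choices
that published threshold-model analyses do not fully specify.

## Exact-test contrasts

Fisher tests are two-sided by the "probability ≤ observed" rule (the
convention shared by standard implementations, so results reproduce
across languages). A zero margin returns p = 1 with a degenerate flag.
The reported odds ratio carries a 0.5 continuity correction so it stays
finite with empty cells; the correction never touches the p-value. The
focal unit is subtracted from the genome-wide background before
testing, so a family is never tested against a background containing
itself. Benjamini–Hochberg correction is applied within each battery
(per-family, per-category, per-clade) separately.

For yeast-clade loss depletion, "ancestral" is the copy count at the
node preceding the clade's stem, and clade losses include the stem
branch. Two retention summaries are reported because the natural
definitions differ: the Fisher table uses ancestral − losses, while the
percent-retained column uses the mean extant copy number of the clade's
terminals. With duplications inside the clade, losses can exceed the
ancestral count; the retained cell is floored at zero in that case and
the raw numbers are reported unmodified.

## Rate screen

Per-family duplication rates are duplications divided by branch length,
formed only on pre-origin, origin and post-origin internal branches —
terminal branches and the excluded outgroup never enter, and a
zero-length included branch is an error rather than a silent floor.
Each family is tested by a one-way permutation ANOVA across the three
node classes (treatment df = 2): F is the usual between/within
mean-square ratio, its null distribution comes from uniformly permuting
class labels across branches (the total sum of squares is permutation-
invariant, so only the between-class component is recomputed), and p
uses the add-one estimator so it is never zero. The published
description of this screen calls the test "two-factor" while giving the
degrees of freedom of a single three-level factor; the per-family
one-way reading is implemented here and documented rather than asserted
as the original computation.

A family is a candidate iff it is conserved (≥ 1 copy in ≥ 70% of
filamentous taxa, boundary inclusive) AND its Dollo origin lies at an
origin node OR its rate signal is significant (raw p < 0.05, with BH q
reported alongside) *and directional* — the origin-class mean must
strictly exceed both other class means. The directionality filter is
deliberate: the screen targets elevated duplication at the origin, and
an undirected F-test would admit families whose rates are elevated
elsewhere. It makes the candidate-by-rate fraction conservative
(below α) under the null; the type-I error of the permutation test
itself is the calibrated quantity.

Branch lengths differ across branches, so null rates are independent
but not identically distributed (shorter branches have noisier rates)
and the permutation test is approximate for this design — a property
inherited from the rate definition itself. Empirically, at the study
conditions used in the acceptance checks (16 taxa, families gained at
the root, matched overall event budget) the realised type-I error sits
inside the 95% binomial interval of α = 0.05.

## Feature statistics

Gene models come from GFF3 (1-based inclusive): one model per gene,
keeping the longest mRNA (by genomic span, ties broken by id) when
several exist — a deterministic rule where no convention is published.
Introns are the gaps between consecutive CDS segments in genomic order;
UTRs are ignored throughout, since the statistics are defined on CDS
coordinates. Minus-strand genes keep genomic intron coordinates, with a
transcript-order accessor for order-sensitive summaries.

Length contrasts use Welch's t-test (unpooled variances,
Welch–Satterthwaite df). The published description — "Welch's t-test
with pooled variance estimation (var.equal = FALSE)" — contradicts
itself; `var.equal = FALSE` *defines* the unpooled test, so Welch is
what is implemented.

A domain architecture is the ordered tuple of domain accessions along a
protein; (A,B) and (B,A) are distinct. Within each (family, group), an
architecture is retained only if present in ≥ 70% of that group's
species carrying the family. Domain-count contrasts fit a per-family
Poisson GLM with a log link (the canonical count model; the source
analysis names only "GLM") and test the group coefficient by likelihood
ratio; degenerate fits (no count variation, unbounded coefficients)
return p = 1 with a flag rather than crashing. Poisson-vs-observed
dispersion is the caller's diagnostic to check when counts are strongly
overdispersed.

## Synthetic data: what it emulates, and what it does not

The generator produces the study conditions the analyses assume. A
species tree of 12 taxa (16 for screen studies) with lognormal branch
lengths centred on 0.2 substitutions/site; three nested origin nodes on
the backbone, below at least one pre-origin split. Families gain once
at a sampled node; along each branch the family accrues duplications as
Poisson(λ_d × length × elevation) events, each splitting a uniformly
chosen live copy, while each copy independently runs a loss clock of
rate λ_l. Branch-level Poisson duplications keep each family's
per-branch *rate* centred on λ_d × elevation regardless of accumulated
copy number — the quantity the screen actually tests. Defaults are
λ_d = 0.5, λ_l = 0.4 (about 0.1 duplications and 0.08 loss events per
copy on a background branch — smaller-magnitude dynamics than real
genome-wide catalogues, but in the regime where most families show few
or no events, as observed). Screen power studies set the elevation to
10 and size λ_d so that ten-fold elevation yields 20 expected
origin-branch events; the matched null keeps that λ_d with elevation 1.
Fully extinct families are redrawn and counted, making the acquisition
bias explicit.

The simulator records two event sets. The *raw* history (every Poisson
event) calibrates rate expectations. The *observable* history is the
parsimony-canonical reading of the pruned surviving gene tree: a
duplication whose evidence is erased by complementary losses is
unidentifiable in principle, and surviving events are placed at their
lowest consistent position. Reconciliation of the true gene tree is
required to reproduce the observable set exactly, branch by branch —
a cross-check of two independent implementations of the same theory
(one on simulator structures, one on parsed Newick), not a claim that
parsimony recovers the raw history.

Traits evolve by forward Brownian motion of the liability; gene models
and domain tables are drawn with group-dependent distributions (introns
75 vs 110 bp, domain counts 2 vs 3 on average for unicellular vs
multicellular groups — shifts of the magnitude the feature statistics
are meant to detect).

What passing these tests shows: the event bookkeeping is exact, the
statistical primitives match independent oracles, the screen has its
nominal error rate and stated power *under the generative model*. What
it does not show: robustness to gene-tree estimation error beyond the
NNI-style perturbations exercised in the tests, to family clustering
artifacts, to model misspecification in the trait process, or to the
deep-time branch-length uncertainty of real fungal phylogenies.

## Problem sizes

The bundled analyses run at desk scale by choice: 12–16 taxa,
200–500 families per study, 999 permutations, 100,000 MCMC generations
(3,000 per replicate inside the 300-replicate calibration study). All
generators and samplers are bit-reproducible under a fixed seed, and
every simulation in the test suite and acceptance script states its
conditions inline.

## Known limitations

- The polytomy resolution is greedy, not an exhaustive
  duplication-loss search; adversarial polytomies exist where it is
  suboptimal.
- Presence-only families assign all surplus copies to terminal
  duplications; internal duplication history is invisible without a
  gene tree.
- The screen's p-values are approximate under branch-length
  heteroscedasticity (see above) and carry no phylogenetic
  autocorrelation correction.
- The threshold-model sampler fixes the diffusion rate; it does not
  sample it, and multi-state ordered thresholds are out of scope.
- The yeast-loss report's two retention definitions can disagree when
  clades expand after simplification; both are reported rather than
  adjudicated.
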