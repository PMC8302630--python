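# Methods

This note documents the models implemented in `protokaryo`, their
assumptions, the defaults that matter, and what the synthetic validation
does and does not demonstrate.

## Data model

All statistics are gene-granular: coordinates are carried (0-based
half-open) but only the *order* of genes along a scaffold enters any
computation, because macrosynteny evidence is counted in genes, not base
pairs.  Homology input is a flat list of gene-id pairs; a pair is an
orthologue or a paralogue purely according to whether its two genes belong
to different species or the same species.  Pairs naming unknown genes are
dropped (with a logged count) rather than rejected, to tolerate
annotation-version drift; gene ids must be globally unique so that bare
id pairs resolve unambiguously.  Species roles (one non-duplicated
`reference`, the duplicated `post_wgd` genomes, optional `comparator`
genomes used only for segmentation labelling) are always declared in
configuration, never inferred.

## Segmentation

Each gene of a target scaffold is labelled, per comparator genome, by the
comparator chromosome holding the majority of its co-orthologues ("none"
if it has no orthologue; ties broken to the lexicographically smallest
chromosome and flagged).  "none" is a regular category — a run of
orthologue-free genes is itself evidence of homogeneity.

A scaffold is modelled as a concatenation of segments, each emitting its
labels i.i.d. from a segment-specific categorical distribution with a
symmetric Dirichlet prior (concentration `dirichlet_concentration`,
default 0.5) over the label alphabet of its track; independent comparator
tracks multiply.  The score of a segmentation is the sum of per-segment
Dirichlet-multinomial log evidences minus `segment_penalty` (log units,
default 3.0) per breakpoint.  The optimal breakpoint set is found exactly
by an O(n²) dynamic program; a brute-force search over all 2^(n−1)
segmentations is kept in the test suite as the oracle.  The penalty
default is calibrated so that a 10-gene scaffold with a single stray
label (5% noise) is never split.  Breakpoints are between-gene positions
(a breakpoint *i* separates order index *i* from *i*+1), which makes the
two-pass breakpoint union well defined.  Scaffolds with fewer than
`min_genes_per_scaffold` (default 10) genes are carried unsegmented.

Segmentation runs twice — within-clade comparators, then outgroups — and
the final segments are defined by the union of the two breakpoint sets,
so both lineage-specific and deep rearrangement boundaries survive the
merge.  The changepoint model here is this package's own concrete
instantiation of "segments have homogeneous orthologue composition"; it
is deliberately the simplest exact-DP model with that property.

## The macrosynteny mixture model and CVB0

Reference segment *s* draws the ancestral chromosome of each of its genes
from a segment-specific distribution with Dirichlet prior α_k (default
0.1); a gene from chromosome *k* scatters its co-orthologues over the
segments of post-WGD species *t* according to a chromosome-specific
distribution with Dirichlet prior β_c^(t) (default 0.1).  The observed
count tensor n_{t,c}^{s,g} caps each gene at D^(t) co-orthologues per
species (default 4, matching the expected 1-to-4 relation after two
WGDs); excess partners are dropped by descending homology score, ties by
lexicographic id.  A hyperparameter slot `L` (default 10) is carried in
the configuration and logged for compatibility with earlier formulations
of the model, but has no effect on the computation here.

Inference is zeroth-order collapsed variational Bayes.  With pseudo-counts

    ahat_k^(s)   = alpha_k + sum_{g' in s} q_{s,g'}(k)
    bhat_c^(k,t) = beta_c^(t) + sum_{s,g} q_{s,g}(k) * n_{t,c}^{s,g}

the update for gene (s, g) is

    log q(k) = log(ahat_k^(s) - q(k))
             + sum_{t,c} sum_{i=1}^{n_{t,c}} log(i-1+bhat_c^(k,t) - q(k) n_{t,c})
             - sum_t sum_{i=1}^{n_t} log(i-1+sum_c bhat_c^(k,t) - q(k) n_t)

normalized to unit sum; the "−q(k)" terms are the exact leave-one-out
correction.  These pseudo-count forms (prior plus responsibility-weighted
counts) are the unique ones under which the subtraction removes exactly
the gene's own contribution; the normalized ahat and bhat rows serve as
the reconstruction confidence scores U[s,k] and V[t][k,c], and hard
assignments take argmax over k (ties to the lowest index, flagged).

Numerical/operational choices:

* responsibilities are initialized per-gene Dirichlet(1), seeded;
* the prior is annealed — at sweep j the effective α is α_k + 0.8^(j−1)
  while j < 98, exactly α_k afterwards — to avoid early commitment to a
  poor mode;
* genes are updated in a fixed segment-major order for reproducibility;
* sweeps stop when Σ_{s,g,k} |q − q′| < 0.001 or after 100 sweeps (all
  four constants overridable);
* any non-positive log argument raises immediately (it indicates a prior
  too small for the data or corrupted bookkeeping, never a state to
  silence);
* the sweep kernel is numba-compiled; a pure-Python evaluation of the
  same update (`cvb0_update_gene`) is kept as an independent arithmetic
  path and cross-checked in the tests to 1e−12.

K is selected by refitting over a K range (three restarts each, keeping
the most significant) and scoring each reconstruction by a hypergeometric
tail: with g gene pairs and p paralogue pairs in a post-WGD genome, and v
gene pairs lying on same-assigned-chromosome segment pairs, the tail
P(X ≥ x) of the observed same-chromosome paralogue count x under uniform
scatter; log tails sum over species and the smallest (most significant)
total wins, ties to the smallest K.

## Hypergeometric machinery

All enrichment questions share one kernel: P(X ≥ x) for x marked pairs in
a focal class of n out of g candidate pairs carrying m marked pairs in
total.  Unordered pairs throughout; "gene pairs between segments A and B"
is |A|·|B| (C(|A|,2) within a segment), and g is the genome-wide total on
the same scale.  Screening uses the strict threshold tail < 1e−5 and no
multiple-testing correction (raw thresholds are intentional: the
screening output feeds combinatorial constraints, not discovery lists).
The default path evaluates scipy's log-space survival function; an exact
rational mode (integer binomials) backs the oracle tests and the scenario
DP.

## Proto-chromosome refinement

Within one ancestral chromosome's segment group:

1. significantly paralogous segment pairs (tail < 1e−5) are *forbidden*
   to share a descendant chromosome;
2. attraction evidence is applied in tiers — cross-species orthologous
   pairs in ascending tail order, then same-scaffold pairs, then pairs
   sharing a linkage group — by greedy single-linkage merging that
   refuses any merge uniting a forbidden pair (equal significance broken
   by segment ids; an edge both forbidden and attracting stays
   forbidden and is logged);
3. clusters with fewer than 5 genes are dropped;
4. every set partition of the clusters is enumerated by restricted
   growth strings with forbidden-pair pruning (unconstrained, the count
   is the Bell number; groups above `max_clusters`, default 15, are kept
   as one flagged proto-chromosome rather than searched);
5. each partition is scored by the product of per-species tails of
   inter-block paralogue counts and per-species-pair tails of same-block
   orthologue counts; factors with no candidate pairs are neutral (1).
   The smallest product wins; exact ties break toward fewer blocks, then
   enumeration order.

For gnathostome-style reconstructions the paralogue factor can be
restricted to "red" block pairs — pairs expected to share duplicated
material under a declared fusion/fission history.  No constructive rule
for redness follows from first principles, so two rules are provided:
the default treats every inter-block pair as red (reducing to the
unrestricted test), and a caller-supplied predicate can encode a specific
rearrangement hypothesis.  Proto-chromosomes with segments from fewer
than 3 species can be filtered as unreliable (`filter_subgroups`).

The multiplicity Y_k of ancestral chromosome k is the number of
proto-chromosomes it produced, with gene counts and genome fractions per
chromosome.

## The duplication-scenario test

The null: after polyploidization leaves N copies of each of K ancestral
chromosomes, single chromosomes duplicate independently — at each step
every extant chromosome is equally likely — until Y chromosomes exist.
The number of ordered histories reaching a multiplicity vector (Y₁…Y_K)
factorizes as a multinomial interleaving times per-chromosome ordered
history counts Γ(Y_k)/Γ(N); the total is Γ(Y)/Γ(X), X = KN.  The
reported probability P(δ ≤ D | ΣY_k = Y), with δ the total absolute
deviation from the ploidy level M, is a ratio of astronomically large
integers and is computed in exact rational arithmetic by a dynamic
program over (chromosome index, total assigned, deviation budget); the
per-chromosome support is bounded by N ≤ Y_k ≤ M + D.  The probabilities
at issue are ~1e−5, so floating point is never trusted here; tests check
the DP against explicit vector enumeration (rational equality) and
against Monte-Carlo simulation of the sequential process.

Named scenarios evaluate a 17-chromosome observed vector under N ∈ {1,
2, 4} with M = 6, and its integer-halved counterpart (floor, clamped at
max(1, N)) under N ∈ {1, 2} with M = 3 — the halved vector represents
histories in which a final tetraploidization doubled pre-existing
multiplicities.  Optional variants append an eighteenth chromosome at
multiplicity max(1, N), or restrict to the five largest, most reliably
reconstructed chromosomes (K=5, Y=30, D=0).  In pipeline runs the
expected ploidy M is the modal reconstructed multiplicity and N ranges
over the configured candidates.

One symbol clash is worth flagging: the total history count Γ(Y)/Γ(X) is
named `total_histories` in code; T elsewhere denotes the number of
post-WGD species.

## The simulator

`protokaryo.simulate` grows extant genomes from a single ancestor
(default 18 chromosomes — the reconstructed proto-vertebrate karyotype —
of 100 genes each).  Per-branch event programs apply whole-genome
duplication or triplication (hexaploidy is modelled as one triplication
event; serial-hybridization alternatives can be expressed as successive
events), programmed or random fusions/fissions/translocations, and
Poisson-count random interval reversals for intra-chromosomal shuffling.
Gene loss is per-copy Bernoulli; allopolyploid bias applies two retention
probabilities keyed on the subgenome tag of the last polyploidization,
with the configurable ratio between them defaulting toward the ~2.25
retained-gene ratio observed between 2R subgenomes.  A `keep_one` flag
guarantees each ohnologue group survives in every species.  One seeded
`numpy` Generator drives a whole run.

Homology emission is divergence-aware: orthologues are cross-species
pairs sharing an ancestral gene *and* agreeing on the subgenome tags of
polyploidizations shared by both lineages (identical leading WGD events
in two branch programs are treated as shared, pre-split events), so
lineages that split before any WGD show 1-to-many orthology (capped at
the co-orthologue limit, default 4) while lineages sharing their WGDs
show 1-to-1 orthology between corresponding subgenome copies.  Noise
removes true pairs and adds uniform spurious pairs at a configured
fraction.

What the simulator does *not* emulate: sequence-level divergence and
alignment artefacts, assembly fragmentation beyond what fissions create,
gene-family expansion by tandem duplication, delayed rediploidization
genealogies, and realistic orthology-caller error structure (noise is
uniform, not similarity-correlated).  Passing the recovery tests
therefore shows the algorithms are correct and calibrated on clean-ish
evidence of the assumed structure, not that real genome-scale inputs
would yield the same accuracy.

## Validation scale

The genome-scale reconstructions that motivated this package (hundreds of
segments, nine species) are not reproducible from printed inputs, so the
test suite validates parameter recovery at desk scale: 6 ancestral
chromosomes × 150 genes with two post-1R species (retention 0.8, 5% pair
noise, 20 seeded runs) for K selection and assignment accuracy, and
3 × 80 genes with tetraploidization + hexaploidization for multiplicity
recovery and the scenario verdict.  These sizes keep the full suite
around half a minute while leaving every statistic in the regime where
its asymptotics have not yet washed out (segments of tens of genes,
hypergeometric counts in the hundreds).

## Known limitations

* The set-partition search is exponential (Bell numbers); groups beyond
  the enumeration cap are reported unpartitioned rather than searched
  heuristically.
* `select_k` refits the model for every K and restart; on large tensors
  this dominates runtime.
* The scenario test conditions on the total chromosome count Y and treats
  chromosome loss as absorbed into the observed multiplicities; it does
  not model chromosome-scale deletions explicitly.
* Orthologue/paralogue inference itself (similarity search, tree
  reconciliation) is out of scope: pair lists are consumed as given.
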