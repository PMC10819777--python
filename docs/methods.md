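# Methods

## Genus resolution

NCBI taxonomies do not give every species a `genus`-ranked ancestor.
`resolve_genus` therefore walks from the species toward the root and
returns the first ancestor ranked `genus`; the walk stops at the first
ancestor ranked `family`, `subfamily`, `tribe` or `subtribe` (the
"family-level barrier"). If the barrier is reached without meeting a
genus, the `no rank`/`clade` ancestor *closest to the species* inside
that window is returned instead — the most specific unranked grouping
above the species, which is the closest analogue of a genus. Where
several unranked candidates exist the closest-to-species choice is a
design decision (an equally defensible convention would take the one
just below the barrier); it is deliberately the most specific grouping,
which keeps genus-level database expansion conservative. An unranked
node qualifies only when a family-level barrier is eventually met — a
walk that reaches the root without one returns no genus, since an
unranked node directly under the root is a domain-scale grouping, not a
genus. Rank tokens are compared exactly (case-sensitive, trimmed);
intermediate ranks such as `subgenus` or `species group` are skipped and
act as neither targets nor barriers.

## Assembly selection

Candidates flagged `excluded_from_refseq` are removed first. Survivors
are ordered lexicographically by RefSeq category (reference genome >
representative genome > na, with empty/"NA" normalized to `na`
case-insensitively), assembly level (Complete Genome > Chromosome >
Scaffold > Contig), and most recent release date. Remaining ties break
on ascending accession — an arbitrary but reproducible convention, since
summary files carry no further ordering information. Unknown category or
level tokens are an error rather than a silent worst-rank: summary-file
dialect drift should be loud. The genus fallback pools the congeners'
candidates and applies the identical ranking.

## Keep-lists

A species is *detected* when its relative abundance exceeds a threshold
(default 0, i.e. strictly positive) in at least one sample; the
threshold is a parameter because marker-based profilers already apply
their own detection floor. Species-level keep-lists are the detected
species intersected with the catalog. Genus-level keep-lists are the
species-level set plus every catalog species whose resolved genus
matches a detected species' genus. Detected species whose genus cannot
be resolved stay in the list but are not expanded; this keeps the
genus-level list a superset of the species-level list, which the
subsetting logic treats as an invariant. Detected names with no taxID
mapping are reported and skipped, never fatal.

## Tree grafting

Placement operates on a rooted tree with branch lengths whose leaves are
labeled by species taxID. The root's stem length is forced to zero: a
root edge has no meaning for leaf-to-leaf distances and breaks the
correspondence between branch sums and UniFrac normalizers.

The reference group of a missing species is found by walking its lineage
upward and collecting, at each ancestor, the tree leaves whose lineage
contains that ancestor; the first non-empty set wins (congeners when the
genus is represented, confamilials otherwise, and so on).

* |G| = 1 — midpoint mechanism: the anchor leaf's branch of length L is
  split by a new inner node at L/2 and the new leaf attaches to it with
  length L/2. The new leaf sits at distance L from the anchor and every
  pre-existing pairwise distance is unchanged (per-branch the split is
  exact in binary floating point; summed path lengths can differ in the
  last bit because the association order changes).
* |G| ≥ 2 — maximization mechanism: every node (internal and leaf) is
  scored by purity |leaves(n) ∩ G| / |leaves(n)| and inclusiveness
  |leaves(n) ∩ G| / |G|. These leaf-fraction forms are one concrete
  operationalization of clade purity/inclusiveness; they are isolated in
  a single scoring function so alternates can be swapped. Among nodes
  with inclusiveness strictly above the floor (default 0.6, compared as
  the exact rational 3/5 against exact rational scores, so a node at
  exactly 60% is excluded) the maximizer of purity + inclusiveness wins;
  ties prefer higher purity, then fewer descendant leaves (the most
  specific clade), then the smallest canonical node id. Node ids are
  assigned by a preorder that visits children in order of their smallest
  descendant leaf label, so the tie-break is invariant under any
  serialization of the same tree. The root's inclusiveness is 1, so
  selection never fails for a floor below 1.

A selected internal node receives the new leaf as an additional child (a
polytomy) with branch length equal to the mean distance from the node to
the G members *descending from it* — members outside the clade would
route through the attachment point's parent and inflate the estimate. A
selected leaf routes to the midpoint mechanism. With the default 0.6
floor and |G| ≥ 2 a leaf can never satisfy the constraint (its
inclusiveness is at most 1/2); the routing exists for lower floors.

Batch augmentation processes species in ascending taxID order, and each
grafted leaf immediately becomes a candidate reference-group member for
later species. Sequential placement in a fixed order is a reproducibility
choice; batch placement against the original tree only would be equally
defensible but makes the outcome depend on which species happen to be
missing together.

## Diversity metrics

* Shannon entropy uses natural log by default (nats); the base is a
  parameter.
* Faith's PD uses the rooted convention: the sum of branch lengths of
  the minimal subtree connecting the observed leaves *and the root*, so
  a single observed species contributes its full root-to-leaf path. An
  unrooted variant (branches strictly between observed leaves) is behind
  a flag. The rooted form matches the scikit-bio reference, against
  which the implementation is cross-checked.
* Weighted UniFrac is the normalized variant, forced by its use as a
  [0, 1]-bounded distance: with p_s(b) the fraction of sample s's total
  abundance under branch b, the distance is
  Σ l_b |p_x(b) − p_y(b)| / Σ l_b (p_x(b) + p_y(b)). Distance matrices
  are computed from a branch × species incidence matrix so the all-pairs
  cost is one matrix product plus O(pairs × branches) arithmetic.
* Median-of-ratios size factors follow the DESeq2 construction: the
  pseudo-reference is each feature's geometric mean across samples,
  restricted to features positive in every sample; a sample's factor is
  the median of its ratios to the reference. A fallback for sparse
  tables (geometric means over positive entries only, median over
  features positive in the sample) is behind a flag. Note the
  normalization is inherently *relative*: scaling a single sample by c
  multiplies its factor by c^(1−1/n) and its factor ratio to any other
  sample by exactly c, while scaling the whole table leaves all factors
  unchanged — the geometric-mean reference absorbs global constants.
* Mann–Whitney U uses exact null enumeration when the pooled sample is
  tie-free and no larger than 20, otherwise the normal approximation
  with tie and continuity corrections (delegated to scipy). BH
  adjustment is statsmodels' step-up implementation.

## The LD/HD power analysis

`diversity_power_comparison` computes α-diversity (Shannon, Faith's PD)
per sample on raw counts and β-diversity (Bray–Curtis, weighted UniFrac)
on size-factor-normalized counts, compares groups with Mann–Whitney, and
BH-adjusts the four p-values as one family. The β comparison contrasts
the within-group pairwise distances of the two groups — two populations
of C(50, 2) = 1225 distances. These pairs share samples and are
therefore not independent: under a true null the variance of the rank
statistic is inflated by roughly n_pairs/n_samples (~25 here), so the
nominal β p-values are strongly anti-conservative and should be read as
descriptive effect summaries, not calibrated error rates. The α
comparisons use independent per-sample values and are calibrated. On the
default design the phylogeny-aware metrics separate the groups by
hundreds of orders of magnitude, dwarfing the dependence artifact, while
Shannon stays null; Bray–Curtis, being both phylogeny-blind and
pair-based, fluctuates around small nominal p-values that reflect the
dependence, not a real effect.

## Synthetic data

The community simulator draws one log-normal variate per species and
sample — underlying normal mean 1 (the standard simulator
parameterization; a flag reinterprets the mean as the log-normal
expectation instead) and σ as configured — and normalizes within sample.
Read counts are multinomial at fixed depth: read-level simulation
(sequences, error models) is deliberately replaced by count sampling,
because everything downstream consumes counts. Passing tests on these
fixtures therefore demonstrates correctness of the statistics on counts,
not robustness to classification error or sequencing artifacts.

The LD/HD fixture uses 18 species in genus sizes [10, 8] (LD) versus 18
singleton genera (HD), σ = 2, 50 samples per group, 100 000 reads per
sample. Its taxonomy places each genus under its own family; its tree
gives every genus a clade whose members coalesce within depth ≤ 0.1
while genus stems reach depth ~0.8–1.0 (so within-genus patristic
distances ≤ 0.2, between-genus ≥ 1.6). The depths are parameters chosen
to give a clear phylogenetic contrast between designs, not estimates of
real 16S divergence.

All generators are pure functions of their integer seed; fixture files
(profiles, dumps, catalogs) are emitted as text and round-trip through
the package's own readers.

## Problem sizes

Default verification runs use trees of 4–15 leaves for oracle
equivalence scans (1000 instances), 100 random instances for
reference-implementation agreement, exhaustive Mann–Whitney enumeration
up to group sizes of 8, and 20 seeds of the full 100-sample LD/HD
design — sizes at which the brute-force oracles remain exact and the
whole suite runs in seconds.

## Known limitations

* Purity/inclusiveness are leaf-count fractions; abundance- or
  branch-length-weighted variants are not implemented.
* Grafting attaches to internal nodes as polytomy children; edge
  splitting above the selected node is a documented alternative.
* The β group comparison inherits the pseudo-replication of pairwise
  distance units (see above); a permutation test on sample labels would
  be calibrated but is out of scope.
* External classifiers and aligners (database building, read mapping,
  tree inference) are out of scope: the package prepares and consumes
  their file formats but never invokes them.
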