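# Methods

This note documents the models and procedures implemented in
`cladesig`, the parameters that matter, and the design choices made
where the underlying methodology leaves room.

## Pairwise alignment and identity

All pairwise scores use BLOSUM62 with affine gap penalties: a gap of
length *k* costs 11 + (k − 1)·1, i.e. the open penalty of 11 is
charged for the first gapped position and 1 for each extension. Global
alignments penalize terminal gaps. Sequence identity is the fraction
of identical columns among alignment columns, both restricted to the
non-terminal region of the alignment (the leading and trailing
gap-only runs are excluded from the denominator; internal gap columns
count against identity; `X` is never identical to anything). Coverage
of a sequence is the fraction of its residues falling inside the
non-terminal region. These definitions make the "50 % identity / 50 %
length" criterion symmetric and prevent a short fragment from
chaining into a long seed through a high local identity.

The dynamic-programming kernels (global, profile–profile, and local
Smith–Waterman) are numba-compiled; the global and local scores are
cross-checked in the test suite against Biopython's `PairwiseAligner`
configured with the same matrix and penalties.

## Family clustering

Greedy seeded clustering: sequences are visited longest-first (id
ascending on ties, so the order is total and deterministic); each
sequence joins the first existing seed with identity ≥ 0.50 and
coverage ≥ 0.50 *of both sequences*, else founds a new seed. One
member per genome per family is kept — the highest-scoring one against
the seed — and displaced paralogs are recorded. A family is *core*
when present in ≥ 80 % of genomes. A sequence pair whose length ratio
is below the coverage threshold cannot satisfy the coverage criterion,
so such seed comparisons are skipped without aligning; this shortcut
is exact, not heuristic. Real orthology inference (trees,
reciprocal-best-hit) is out of scope.

## Progressive alignment

Guide tree: UPGMA (average linkage) on pairwise 3-mer distances
(1 − shared/min distinct 3-mers). Profiles are per-column residue
frequency vectors; profile–profile scores are the bilinear form
through BLOSUM62, and merges use the same 11/1 affine penalties.
The aligner is deterministic and never produces all-gap columns. It is
a stand-in for production aligners; externally aligned FASTA can be
imported at every stage for fidelity to a specific tool.

## Block trimming ("relaxed" parameters)

A column is *conserved* iff its modal non-gap residue (excluding `X`)
occurs in more than 50 % of rows **and** its gap fraction is ≤ 0.5.
Runs of more than 8 consecutive non-conserved columns split the
alignment; each resulting segment is shrunk to begin and end on
conserved columns and kept if it spans ≥ 5 columns. Kept columns are
reported as 1-based source indices, so trimming is a pure
column-subset operation and is idempotent. All four numbers are
config-exposed (`[trim]` section) because trimming dialects differ
between tools.

## Distances, neighbor joining, rooting, bootstrap

Distances use pairwise deletion of gap columns; `p` is the mismatch
fraction and `poisson` is −ln(1 − p) (error when p ≥ 1, or when a pair
shares no comparable column). Neighbor joining is the canonical
Saitou–Nei algorithm with the Studier–Keppler Q criterion; ties are
broken by the lexicographically smallest active-pair index (leaves in
input order, then internal nodes in creation order), and negative
branch lengths are clamped to zero with the deficit logged. On
additive matrices NJ recovers the generating topology exactly, which
is the module's primary test oracle (including a cross-check against
scikit-bio's implementation).

Midpoint rooting finds the longest leaf-to-leaf path and inserts the
root at its midpoint; when the midpoint falls exactly on an internal
node the root is placed on the adjacent path edge with a zero-length
segment so that the root always bifurcates. Rerooting is implemented
directly (ancestor-chain reversal preserving every edge length)
because the container library's midpoint rooting drops an edge length
when the midpoint coincides with a node.

Bootstrap: columns resampled with replacement per replicate, NJ per
replicate, support of an internal edge = fraction of replicate trees
containing its bipartition; deterministic given the seed.

Distance-based inference here is the built-in stand-in for external
maximum-likelihood tools; trees computed externally can be imported as
newick and used for everything downstream.

## CSI detection

Parameters (defaults): flank window 20 columns per side; ≥ 5 conserved
columns required per flank; conserved column = modal non-gap residue
in ≥ 80 % of scored rows with gap fraction ≤ 20 % (`X` never counts
toward the modal residue); indel intervals of 1–30 columns; zero
tolerated exceptions on either side; display window 80 reference
residues (bounded to 60–100).

The scan enumerates maximal column intervals in which every focal row
carries at least one residue while every outgroup row is entirely
gapped (insertion pattern) or the reverse (deletion pattern), each
side tolerating at most the configured number of exception taxa.
Only runs of columns gapped in all but the tolerated number of rows on
the all-gap side can contain such intervals, so enumeration is
restricted to those runs — an exact necessary condition whose
equivalence with the fully exhaustive scan is property-tested on
hundreds of random alignments. Overlapping candidates of the same
pattern collapse to the widest (leftmost on ties); candidates are
reported sorted by left column.

Two acceptance rules follow:

1. **Flank conservation** — both flanks must contain the required
   number of conserved columns; this encodes the requirement that a
   signature sit in a well-conserved region.
2. **Net length difference** (`require_length_difference`, on by
   default) — the carrier side must have a higher median residue count
   than the gap side across the candidate plus both flank windows. A
   genuine indel is a length polymorphism; this rejects reciprocal
   gap pairs that progressive aligners occasionally place a few
   columns apart in low-complexity or W-rich stretches (which would
   otherwise masquerade as a paired insertion + deletion with zero net
   length change). It is the automated analogue of the visual
   inspection step that discards alignment artifacts.

The indel size range is measured on the residue-bearing side
(ingroup for insertions, outgroup for deletions). Polarity follows
the outgroup state and can be re-examined against external reference
rows: if any external reference disagrees with the outgroup consensus
the call becomes `ambiguous`. The reported *region* is the ungapped
reference-sequence position of the first conserved column in the left
flank window through the last conserved column in the right flank
window, 1-based inclusive — matching how signature tables bound a
CSI by its conserved flanks. Region endpoints therefore depend on the
flank-window width; accession-based comparisons should allow a
one-window tolerance.

Group specificity is always relative to the taxa present in the
alignment; a genome-database-scale search horizon is represented by
whatever outgroup rows the user supplies, and the reports state this.

## CSP detection

From a hit table (12/13-column tabular dialect), per query:
significant = e-value ≤ 1e-5 (config-exposed; the original screens do
not print a cutoff), self-hits excluded. Verdict: *specific* if
significant out-group hits ≤ max_exceptions (default 0); *orphan* if
no significant non-self hits at all; else *not_specific*. Note that
tightening the threshold can demote a specific query to orphan (its
in-group hits lose significance too), so the set of specific queries
is non-decreasing only up to orphan conversions.

The built-in `mini_search` is an all-vs-all Smith–Waterman scan
(BLOSUM62, 11/1) emitting hits at raw score ≥ 60. Its e-value
surrogate uses the published Karlin–Altschul parameters for gapped
BLOSUM62-11-1 (λ = 0.267, K = 0.041): bits = (λS − ln K)/ln 2 and
E = m·n·2^(−bits) with m the query length and n the total target
residues. For fixed search-space size this is a strictly monotone
transform of the raw score, which is all the verdict logic requires.

## Synthetic data generator

The generator emulates the structure of a clade-marker study: an
ingroup and an outgroup Yule subtree (random leaf splitting,
exponential branch lengths, mean 0.03) joined by stems of 0.12;
100 families of 300 residues evolved by 20-state uniform replacement
(per branch, Poisson(rate·length·branch) substitution events at
uniform sites, each replacing the residue with one of the 19 others;
expected pairwise difference after a path of t substitutions/site is
(19/20)(1 − e^(−20t/19)), which the tests verify); 15 CSIs of sizes
1–7 plus one of 20, alternating insertion/deletion, planted on the
ingroup stem at random interior positions; 5 ingroup-restricted genes
evolved on the ingroup subtree only; and 3 random noise proteins per
genome (80–400 residues). With these rates, within-family identities
fall around 0.65–0.98 and between-family identities are at random
expectation, so clustering recovers the manifest exactly.

Planted indels are identical across carriers (a single ancestral
event) and the ±20 residues flanking the edit point are reverted to
the ancestral residues in *all* genomes, guaranteeing that every
planted event satisfies the default conservation rule; the generator
asserts detectability on the by-construction alignment before
emitting. A `hard_mode` flag disables flank locking to measure
sensitivity under undisturbed substitution noise. The generator is
fully deterministic given its seed, down to byte-identical FASTA.

What the simulator does **not** emulate — and hence what passing tests
do not demonstrate about real data: realistic indel length
distributions and alignment ambiguity around them, rate heterogeneity
across sites and lineages, domain-level homology (recombination,
fusion), paralogy beyond simple duplication, and database-scale search
horizons. Recovery statistics on synthetic data are an upper bound on
real-data performance.

## Problem sizes and determinism

The shipped study conditions (20 genomes × ~108 proteins) imply about
10^5 global alignments during clustering and 2×10^5 local alignments
in the CSP screen; with the compiled kernels the full chain runs in a
few minutes on one CPU. All randomness flows from explicit seeds;
reports are byte-identical across reruns with the same inputs, config
and seed. Larger studies scale quadratically in total protein count;
the module boundaries accept externally computed intermediates
(cluster tables, alignments, hit tables, trees) precisely so the
expensive steps can be delegated to specialised tools.

## Known limitations

- The progressive aligner is competitive only at high within-family
  identity; low-identity families should be aligned externally.
- Gap costs in profile merges are not occupancy-weighted; very gappy
  profiles can misplace gaps (mitigated downstream by the length-
  difference rule and conserved-flank requirement).
- NJ + Poisson distances are a topology-level stand-in, not a
  substitute for ML inference with empirical substitution models.
- CSP specificity is relative to the supplied universe; absence of
  out-group hits in a small universe is weak evidence compared with a
  database-scale search.
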