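# Methods

## Concordance factors

All bipartition work is done on the unrooted view of the trees: a degree-2
root is suppressed and its two edges merged, because concordance is a
property of unrooted splits. For each internal branch of the binary
reference tree the quadripartition (A, B, C, D) is taken from the two
subtrees on each endpoint and canonically ordered: the side containing the
lexicographically smallest taxon label supplies (A, B), and within each side
the block holding the smallest label comes first. This pins down which
alternative is DF1 (AC|BD) and which is DF2 (AD|BC); the underlying
statistics leave that labelling arbitrary, so tables produced by other tools
may have the two columns swapped relative to ours.

A gene tree is decisive for a branch iff its leaf set intersects all four
blocks. A decisive tree is CONCORDANT when one of its own splits equals
(A∪B)∩L over its leaves L, DF1/DF2 for the two alternatives, and PARAPHYLY
otherwise; at most one of the three resolved categories can hold because the
three splits are pairwise incompatible. gCF is the percentage of decisive
trees that are concordant, and the four gene factors sum to 100 exactly.
Branches with no decisive gene trees (or no decisive sites) are reported as
null and excluded from summaries, never coerced to zero.

Site factors sample `n_quartets` (default 1000) quartets uniformly with
replacement, one taxon per block. A site is decisive for a quartet iff all
four taxa carry unambiguous A/C/G/T (any gap, `?`, `N` or IUPAC ambiguity
disqualifies the site) and the pattern has exactly two states, each twice —
the three such patterns map one-to-one onto the three resolutions. Quartets
with zero decisive sites are excluded from the mean (a 0/0 ratio carries no
information); sN is the mean decisive-site count over the quartets that
contribute. The sEF equality test pools the two alternatives' decisive-site
counts across the sampled quartets, giving one test per branch; a
per-quartet averaged variant was considered and rejected because a single
pooled count is what a per-branch p-value summarizes. An `exhaustive` mode
enumerates every quartet once; sampling is seeded and deterministic.

The equality test is χ² = (n₁−n₂)²/(n₁+n₂) with one degree of freedom — the
standard conditional binomial test of equal frequencies. Under pure
incomplete lineage sorting the two nearest-neighbour alternatives are
exchangeable, so rejection indicates signal beyond the coalescent. With
counts of zero on both sides the test is undefined and reported as such.

Two flavours of per-branch resolution frequencies are provided.
`quartet_frequencies` uses whole-split containment (the same classification
as gCF, with paraphyletic trees excluded from the denominator), matching how
printed per-branch quartet supports are normalized. For calibration against
coalescent theory, `quartet_topology_frequencies` enumerates one taxon per
block and reads the induced quartet topology out of each gene tree; by the
subsampling consistency of the coalescent its expectation for the main
resolution is exactly 1 − (2/3)e^(−T) at a branch of T coalescent units.
Whole-split containment frequencies approach that value only when blocks are
single taxa — with multi-taxon blocks containment is a strictly stronger
event and its conditional frequency sits above the quartet value — which is
why the calibration suite tests the quartet-based statistic. The polytomy
test compares the three resolution counts to equal thirds with a χ² on two
degrees of freedom.

## The simulator

Gene trees are drawn from the multispecies coalescent on a rooted binary
species tree with branch lengths in coalescent units (2N generations = 1
unit, the ASTRAL convention), one sampled lineage per tip — matching
one-transcriptome-per-taxon sampling. Within a branch of length T the k
entering lineages coalesce with exponential waiting times at rate k(k−1)/2;
survivors pass upward; above the root coalescence runs to a single lineage.
The species tree must be ultrametric in coalescent units (validated to
1e-6 relative tolerance): the global-clock coalescent is otherwise
ill-defined, and all shipped fixtures are ultrametric. A substitution scale
μ (substitutions per coalescent unit, default 1.0) converts gene trees to
substitution units for sequence simulation.

Sequences evolve under JC69: a uniform root state and per-branch
substitution probability (3/4)(1 − e^(−4d/3)), with substituted sites taking
one of the other three bases uniformly. Richer models are deliberately out
of scope — no quantity computed here depends on them, and JC69 keeps the
pairwise-difference closed form available as an oracle.

Per-gene taxon dropout removes each taxon independently with probability
`p_miss`; a draw that would leave fewer than two leaves is redrawn for that
gene, so every emitted gene tree is usable (the bias this introduces is
negligible at realistic `p_miss` and only affects genes that would otherwise
be discarded anyway). Rogue injection multiplies a chosen taxon's terminal
branch by a configurable factor (default 20×) in a chosen fraction of genes
and records the planted (gene, taxon) pairs. Orthogroup tables plant an
exact single-copy fraction; the remaining orthogroups draw per-genome copy
counts from a configurable distribution (default Poisson(1.2)) with all-ones
draws rejected, so the planted set is exactly the single-copy ground truth.
Read simulation plants a terminal run of three sub-Q20 bases in a chosen
fraction of reads, on a random end, against an otherwise Q30–Q41 profile.

What the generator does *not* emulate: substitution-model misspecification,
alignment error, indels, gene duplication/loss, introgression and
recombination. Passing tests therefore demonstrate the correctness of the
statistics and filters under the coalescent-plus-noise model, not robustness
of the statistics to every failure mode of real transcriptome data.

## Curation filters

**Read QC.** The end-trimming rule ("trim ends at runs of three consecutive
sub-Q20 bases") does not fully specify behaviour when low-quality windows
sit away from the read ends. We resolve it as: repeatedly locate the
three-base sub-Q20 window closest to either end and remove it together with
the (shorter) segment between it and that end, until no such window remains;
ties trim the 3′ side. This is deterministic, idempotent (the output
contains no qualifying window), and reduces to plain end-trimming whenever
low-quality runs are confined to the tails — the planted and the typical
Illumina case. Discards then apply in order: median quality < 22 (lower
median for even lengths — the even-length median is otherwise unspecified),
more than 3 uncalled bases, length < 40 bp.

**Isoform filter.** An isoform is retained iff its FPKM is at least 1% of
its parent gene's total; the denominator (gene total rather than sample
total) is a choice, exposed as `min_fraction` with the comparison done in
percent space so the exact-1% boundary is retained rather than lost to
binary rounding of 0.01.

**Consensus scaffolding.** Reference-guided scaffolding is replaced by
reference-free overlap consensus: every pair of transcripts is aligned with
a free-end-gap (overlap) pairwise alignment; identity is computed over
aligned non-gap columns. One overlapping pair below the identity threshold
(default 0.95) makes the whole sample MISSING for that orthogroup — a
conservative reading of "divergent assemblies are treated as missing data".
Otherwise sequences are merged progressively into per-column base counts:
majority base per column, ties encoded as IUPAC ambiguity codes,
non-overlapping fragments concatenated in input order. The verdict
(consensus vs missing) is order-invariant because it is decided from the
full pairwise matrix before any merging.

**Occupancy trimming.** Each iteration removes columns below 90% residue
occupancy, then sequences whose residue count is below 90% of the current
width, then re-aligns survivors (the default realigner keeps surviving
columns, which makes the procedure a pure filter; any callable mapping
sequences to an alignment can be plugged in). The loop stops at a fixed
point or after 10 iterations; counts are monotone non-increasing, and an
alignment emptied by the rules is returned as an explicit empty result.

**Rogue filtering.** For each (gene, taxon) the signature is the relative
diameter collapse (diam(T) − diam(T∖taxon))/diam(T), where diameter is the
maximum leaf-to-leaf path length. A pair is flagged iff the signature
reaches an absolute floor (default 0.5 — the taxon alone accounts for half
the tree's depth) *and* exceeds the per-taxon empirical 0.95-quantile of the
null portion of that taxon's signature distribution (signatures below the
floor). Estimating the quantile from the sub-floor null keeps the threshold
meaningful when many genes of one taxon are genuinely aberrant — a raw
quantile would sit inside the outlier cluster and mask most of it. Taxa seen
in fewer than three gene trees, and gene trees with fewer than four leaves
(whose diameter signatures are degenerate), are never flagged. This is a
deliberately simplified per-species analogue of long-branch rogue detection,
not a reimplementation of any specific tool's optimization; flagged leaves
are pruned per gene, never globally, and pruning that would leave fewer than
two leaves is skipped (flags still reported). The signature floor assumes
the deep-divergence regime of real phylogenomic gene trees, where species
divergences span many coalescent units and natural diameter variation is
small relative to a 20× terminal branch; under shallow histories with
extreme ILS the coalescent tail itself can produce large signatures.

**Completeness filter.** Gene trees with fewer than `min_taxa` leaves are
dropped (boundary inclusive); the floor of 4 is the smallest informative
tree.

## Orthology accounting

Single-copy circumscription requires a copy count of exactly one in every
reference genome; genes from non-reference genomes never affect the call.
Two-step assignment takes the best hmm hit per query (ties broken by score,
then e-value, then lexicographic orthogroup id — fully specified because
search tools leave it undefined) and uses the best surviving BLAST hit
(e ≤ 1e-5) only to set an agreement flag. Overlap percentages are printed to
one decimal with round-half-up, matching how such tables are conventionally
reported; the element-to-orthogroup mapping between two gene sets is an
explicit input, never inferred.

## Problem sizes and numerics

Shipped fixtures use 4–10-taxon species trees. Calibration suites use 2000
gene trees per point (Monte-Carlo standard error ≈ 0.01 on a frequency) and
500 replicate simulations of 150 genes for the type-I-error check of the
equality test, judged against a 99% binomial envelope around α = 0.05 —
sizes at which every check is sharp while the whole suite runs in well under
a minute. Quartet sampling defaults to 1000 per branch. Percentages are
compared exactly where arithmetic is closed (counts of 1000) and via
standard-error envelopes where Monte Carlo is involved. Ultrametricity is
checked at 1e-6 relative tolerance; the isoform boundary uses a 1e-12
additive slack in fraction space.

## Known limitations

* The MSC simulator is single-lineage-per-species and ultrametric-only; no
  duplication/loss, migration or demography.
* JC69 only; no rate heterogeneity or indels, so alignments are always
  gap-free unless constructed otherwise.
* Consensus scaffolding handles collinear fragments; it does not model
  splice-aware mapping against a reference genome.
* Rogue detection is threshold-based and assumes deep divergences; it is not
  a likelihood-ratio method.
* Protein supermatrices are not implemented (DNA only); the partition writer
  emits RAxML-style files.
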