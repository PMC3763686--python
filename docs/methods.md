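# Methods

## The comparative setting

The package models the relationship between a single-copy legume genome (A)
and a paleopolyploid relative (B) that duplicated after the two lineages
split: every A locus potentially has two B homeologs ("copy 1" and
"copy 2"), subsequently eroded by fractionation (loss of one copy) and
reshuffled by segmental inversions. All stages — search, copy assignment,
map building, synteny detection, polymorphism classification, family
clustering — operate on 1-based inclusive coordinates, matching the printed
physical-map convention (feature position = first nucleotide of the placed
alignment). Minus-strand hits are stored with ascending target coordinates
plus a strand flag, which keeps interval logic simple without losing
orientation.

## Homology search

The built-in search is a classical seed-and-extend design: exact k-mer
matches (default k = 11) between query and target are grouped by diagonal
(band half-width 16) and target position; groups with at least 3 word hits
whose dominant diagonal reaches an ungapped segment score of 25 (vectorized
Kadane scan at match +1 / mismatch −2) define alignment windows, which are
resolved by affine-gap local alignment. A gap of length L costs
`gap_open + L·gap_extend` (defaults −5/−2). Both strands are searched by
reverse-complementing the query; the search score is symmetric under joint
reverse-complementation. Significance is the Karlin–Altschul expectation
`E = K·m·n·e^(−λS)` over the summed target length. λ = 1.28 and K = 0.46
are uncalibrated placeholders appropriate for the default ungapped scoring;
when calibrated statistics matter, import real BLAST outfmt-6 tables via
`io_formats.read_hits_table` — the downstream pipeline is agnostic to the
hit producer. Default filters: E ≤ 1e−30 and alignment length ≥ 150 bp,
applied before chromosome ranking.

Copy assignment ranks chromosomes by their best hit's bit score (ties by
chromosome id for determinism); "duplicated" mode keeps the top two distinct
chromosomes, "single" mode one. A second copy is simply omitted — not an
error — when all significant hits fall on one chromosome, since real WGD
genomes show exactly that after fractionation. Within a kept chromosome,
hits chained within 250 kb of the top hit form one tandem cluster,
sub-labeled a, b, c… by start coordinate; 250 kb comfortably contains
reported legume tandem arrays (tens of kb) while separating unrelated loci,
and is exposed in configuration because no principled universal value
exists.

## Maps and synteny

Map coverage is defined as end − start (not end − start + 1): this is the
span between the first and last mapped feature and reproduces published
coverage cells exactly. Published chromosome-level tables bundled in
`datasets.py` carry only feature counts and start/end positions; coverage is
always recomputed. One published table's per-chromosome counts sum to 505
although its printed total row says 507; the package reports computed sums
and never reconciles to a printed total.

Anchors pair every A placement of a query with each of its B copy
placements (a cluster's representative is its first member by coordinate).
Block detection chains anchors per chromosome pair: anchors sorted by A
position, longest strictly-monotone chain in B position extracted greedily
in both directions, allowing up to `max_rank_gap = 2` consecutive
out-of-order anchors to be skipped (rank-based rather than bp-based, because
anchor density is sparse and no distance rule is defensible). Chains of ≥ 3
anchors become blocks; orientation is the chain direction; leftovers are
reported as shared singletons/doubletons, never blocks. Tie-breaking is
fully deterministic: longer chain first, forward preferred over reverse at
equal length, then the lexicographically smallest anchor-index tuple — a
rule chosen because a brute-force enumeration oracle can reproduce it
exactly. A block's copy label is the majority label of its anchors: per-query
labels on one chromosome pair can disagree when the two homeologs score
similarly, while the panel side of a block (left = copy 1, right = copy 2 in
the comparative-map layout) is a property of the chromosome pair.

A locus with no significant hits can be placed tentatively between two named
flanking markers; the interval is tagged tentative and errors name any
missing marker.

## Allelic polymorphism

Allele pairs are aligned globally (match +2, mismatch −3, gap −5/−2 —
explicit because hand-curated alignments are irreproducible). Event
conventions: each maximal gap run is one event regardless of length;
deletions are reported as (last reference base before the run, length);
insertions as the query-coordinate range of inserted bases; SNPs at their
reference coordinate; columns containing N emit no variant. Gap runs are
left-normalized (shifted left while the base preceding the run equals its
last base) so that score-equivalent gap placements yield one canonical
record. Region classification uses the reference gene model: SNP by site,
deletion by first deleted base, insertion by the reference base preceding
the insertion point; an event whose reference extent crosses a region
boundary keeps its first base's region and carries a boundary flag.
Applying the extracted variants to the reference reconstructs the query
exactly — a round-trip invariant the suite checks for arbitrary sequence
pairs.

## Gene-family clustering

Distances are p-distances with pairwise deletion (columns with a gap or N in
either member of a pair are skipped); Jukes–Cantor correction is optional.
The tree is standard Saitou–Nei Neighbor-Joining with the Studier–Keppler Q
criterion; Q ties break on the smallest label pair, negative branch-length
estimates are clamped to zero with a debug note, and the unrooted result is
represented with a degree-3 root. Bootstrap supports resample alignment
columns with replacement, rebuild the NJ tree per replicate, and attach to
each internal bipartition of the full-data tree the percentage of replicates
containing the same split (split semantics, so supports do not depend on
node identity or rooting). Supports are exactly reproducible for a fixed
seed; exact invariance under leaf relabeling holds wherever the label-based
tie-break never binds, which is the generic case for continuous distances.

## The synthetic generator

`synthetic_data` emulates the statistical structure the analysis assumes:

- an ancestral genome (3 chromosomes × 2 Mb by default) with 40 genes and
  30 markers per chromosome placed uniformly without overlap; gene models
  have 4–6 exons with a long first exon, UTRs abutting the coding region;
- genome A = ancestor at 2% substitution divergence; genome B = two
  homeologs per ancestral chromosome at 5% and 8% divergence;
- Poisson(1) inversions per homeolog over windows of 8–14 consecutive
  features (disjoint, never splitting a gene); the floor keeps inverted
  segments at five or more surviving anchors under default fractionation,
  matching the block sizes the recovery tests are stated over;
- fractionation physically deletes 20% of duplicated gene copies
  (coordinates shift; markers and tandem-designated genes are exempt);
- one tandem family of six members spaced 8 kb on one homeolog, mirroring
  reported CHS-like arrays;
- allelic variants injected per region (SNPs: exon 0.003/bp, intron
  0.008/bp, UTR 0.004/bp; indels roughly five-fold rarer, geometric lengths
  capped at 20 bp), kept ≥ 10 bp from region boundaries, ≥ 12 bp apart, and
  placed only in left-normalized, non-repetitive context so that truth
  coordinates are well defined;
- queries are EST-like fragments (600 bp from each gene start) plus full
  marker sequences (300 bp), reflecting the partial sequences such analyses
  typically start from.

Substitutions are uniform over the three alternative bases (no transition
bias): the downstream analysis is rate-insensitive and the bias would only
obscure the recovery measurements. Everything derives from one seed;
identical seeds give byte-identical fixture bundles.

What the simulator does **not** model: repeats and transposons, GC
heterogeneity, segmental duplications other than the configured tandem
arrays, translocations between chromosomes, indel divergence between
homeologs, and gene-structure evolution. Passing recovery tests therefore
demonstrate algorithmic correctness under clean WGD structure, not
robustness to repeat-rich real assemblies — for real data the search stage
is expected to be replaced by BLAST output.

## Evaluation definitions

Copy recovery (duplicated mode) is scored over queries whose both homeologs
survive fractionation: the assigned chromosome pair must equal the truth
pair. Block recovery matches detected to truth blocks (≥ 3 surviving
anchors) greedily one-to-one on the same chromosome pair, requiring
anchor-set Jaccard ≥ 0.5; F1 combines the resulting precision and recall,
and orientation accuracy is scored over matched blocks (reported separately
for inverted segments). Variant recovery requires exact agreement of kind,
position, length and region with the injection truth, plus byte-exact
reconstruction of the variant allele.

## Problem sizes and determinism

Default desk-scale runs (3 × 2 Mb ancestor, 210 queries) complete the full
pipeline in tens of seconds; the planted-homolog experiment uses 100 trials
of a 200-bp, 95%-identity homolog in 100-kb targets; variant recovery uses
50 allele pairs. All stochastic stages take explicit seeds and are
reproducible bit-for-bit.

## Known limitations

- The aligner's λ/K are not fitted; reported E-values are internally
  consistent but not calibrated against BLAST.
- Chaining tolerance (skip ≤ 2) absorbs inversions with ≤ 5 surviving
  anchors into flanking forward chains — the same "minor rearrangement"
  tolerance that makes the rule robust on sparse maps; such micro-inversions
  are reported inside a forward block rather than as separate blocks.
- Insertion coordinates follow the query-coordinate table convention, so
  they are not directly comparable across allele pairs with different
  upstream indels.
- NJ branch lengths from a commercial package on genomic sequences are not
  expected to be reproduced; topology and support semantics are.
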