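# Methods

This note documents the models, default parameters and design choices of
the package; it states no empirical result the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate conventions

All in-memory coordinates are 0-based half-open on the forward genome
strand; GFF3 input/output is 1-based inclusive.  Intron dinucleotides are
stored as read on the forward strand; a minus-strand GT..AG intron
therefore reads CT..AC.

## The synthetic study generator (`simulate`)

The generator emulates a non-normalized, oligo(dT)-primed Sanger EST
project over a small fungal-style genome.  What it reproduces, and the
defaults:

* **Genome and genes.**  5 contigs × 80 kb of uniform random sequence;
  100 genes placed left-to-right with 100–400 b intergenic gaps on random
  strands.  Multi-exon genes have 2 + Poisson(5) exons with log-normal
  exon lengths (median ≈ 170 b, bounds 40–800); 15% of genes are
  single-exon (log-normal, median ≈ 900 b).  Intron lengths are log-normal
  with median ≈ 280 b (σ = 0.55), hard bounds 24–2000 b, matching the
  intron statistics EST studies of basidiomycetes report.  98% of introns
  are GT:AG; 2% draw from the minor classes GC:AG and AT:AC.  Splice-site
  dinucleotides are written into the sequence, oriented by gene strand.
* **Planted isoform events.**  At most one alternative isoform per gene:
  cassette exon (p = 0.10), consecutively skipped stretch (p = 0.06,
  length 2 + Poisson(0.5)), retained intron (p = 0.16; only in genes with
  ≥ 3 exons so the retaining isoform keeps a junction and remains
  strand-assignable), alternative donor/acceptor (p = 0.04 each, shift
  9–30 b into the intron).  Introns flanking a planted event are forced to
  GT:AG because the exclusion isoform pairs the upstream donor with the
  downstream acceptor.  RI dominating CE reflects the intron-definition
  regime typical of fungi.  Rates are chosen so a 100-gene study plants a
  few tens of events; the study itself reports far lower per-gene rates,
  which at 100 genes would leave almost nothing to score.
* **Antisense pairs.**  8% of genes participate in a planted pair
  (convergent : divergent : contained = 0.67 : 0.07 : 0.26, following the
  orientation mix the study reports).  70% of convergent pairs restrict
  the overlap to both members' 3′ UTRs; pair members use canonical sites
  only, and overlap regions are kept intron-free by construction.
* **Libraries and expression.**  Five libraries (5/14/18/30-day dikaryon,
  18-day monokaryon) with depths in the study's proportions
  1,001 : 6,848 : 21,547 : 11,059 : 6,830, scaled ×0.1 (≈ 4,700 reads).
  All libraries share one log-normal (σ = 1) abundance profile — a
  non-normalized library preserves abundance — except planted
  differentially expressed genes: 4 genes get an 8-fold boost in the
  18-day dikaryon library and 3 in the monokaryon library, from an
  elevated baseline so they accumulate ≥ 50 ESTs and are testable.  Within
  a library, per-gene read counts are a single multinomial draw.
* **Reads.**  Lengths follow the study's published quantiles (min 50,
  Q1 593, median 729, Q3 793, max 949) via piecewise-linear inverse-CDF
  sampling.  Fragments are 3′-biased: the insert covers the transcript 3′
  end back to read-length + Geometric(mean 150) bases, emulating oligo(dT)
  priming; reads reaching the 3′ end carry a polyA tail (8 + Poisson(20)).
  Half the reads are reverse-complemented (polyT at the 5′ end).
  Optional artifacts: vector/adaptor remnants at either end, per-base
  substitution errors with exponentially end-degraded quality values
  (truthful per-base error probabilities are emitted as the quality
  sidecar), rare indels, and a contaminant-read fraction.  The default
  configuration is noise-free; the test suite switches noise on where the
  cleaning stages are under test.
* **What it does not emulate.**  Chromatogram-level base calling, chimeric
  clones, paired reads, realistic codon/GC composition, and insert-size
  selection (the study reports 0.5–3.2 kb inserts; reads, not inserts, are
  modelled).  Passing recovery tests therefore demonstrates algorithmic
  correctness under the stated read model, not robustness to every failure
  mode of real Sanger data.

## Cleaning (`preprocess`)

Stages run in fixed order — quality, vector, polyA/T, contamination,
length — with exact per-stage accounting (input = survivors + discards).

* Quality trimming is the maximum-scoring-segment rule at cutoff 0.01,
  ties resolved leftmost; a segment of zero score is kept rather than
  discarded.
* Vector stripping searches both strands of each vector with local
  alignment (match +1, mismatch −1 so hits extend through scattered
  substitutions); a hit of ≥ 16 columns with ≤ 20% mismatching columns is
  removed together with its shorter flank.  The 16-column floor keeps the
  chance of a spurious hit in a random read low; mutated remnant edge
  bases that local alignment cannot attribute may survive (≤ ~5 b).
* PolyA/T removal finds runs of ≥ 10 A's (or T's) with ≤ 1 interruption
  and removes the run plus everything toward the nearer end, at most once
  per end.
* The contamination screen uses Smith–Waterman (Biopython's
  `PairwiseAligner`, +1/−2/−5/−2) against both strands of the contaminant
  set; significance uses the Karlin–Altschul approximation
  `E = K·m·n·e^(−λS)` with the classic ungapped +1/−2 constants λ = 1.33,
  K = 0.621, m = read length, n = database length.  Discard requires both
  identity ≥ 0.90 (over aligned columns, gaps included) and E ≤ 1e-10.
* The length filter keeps reads of ≥ 50 bases, consistent with a reported
  minimum surviving length of exactly 50.

## Spliced alignment (`align`)

A minimal anchored spliced aligner sufficient for the low-divergence
synthetic regime; externally produced alignments can be imported from
match/match_part GFF3 instead.

Exact k-mer anchors (k = 14, step 2) are grouped into diagonal segments
and chained colinearly (weighted longest-increasing-subsequence); both
read orientations are tried and the better placement kept, ties broken by
leftmost genome coordinate then contig id.  Genomic gaps of 20–5000 b
between chained segments become introns; the split point of the unaligned
read gap is chosen to maximize flanking matches plus a +4 bonus when the
intron termini read as a canonical splice class on either strand.  The
search window extends 25 b into both anchored flanks because anchors can
overrun a junction when the sequence beyond it coincides.  Terminal read
fragments too short to seed an anchor (≥ 8 b) are rescued by unique exact
occurrence within intron range that carries a splice-class dinucleotide;
ambiguous placements stay unaligned.  Smaller gaps are absorbed as
mismatch runs or indel runs inside one exon block.  Identity is matches
over aligned columns; coverage is aligned EST bases over EST length; the
well-mapped filter keeps identity ≥ 0.90 AND coverage ≥ 0.90, boundary
inclusive.  The 5000-b intron cap leaves headroom above the ≈ 2 kb tail
of the intron-length distribution.

## Cluster-and-merge (`clustermerge`)

Compatibility of two spliced alignments: at least one intron with both
coordinates exactly equal, and identical intron sets over the genomic
region both alignments cover — an intron of one overlapping an exon of
the other (the skipped-exon case) blocks merging.

Merging is deterministic greedy agglomeration: alignments ordered by
descending intron count, then descending span, then id; a candidate joins
the first transcript whose merged structure it is compatible with.  Two
fixpoints then alternate: mutually compatible transcripts merge, and a
*structure completion* pass lets every alignment extend the exon/intron
structure of each transcript it is compatible with, while still
*supporting* exactly one.  Completion matters because a read covering only
the region two isoforms share is evidence for both structures but can be
assigned to only one; without it the other isoform's chain stays
truncated.  The outcome is order-invariant (verified by permutation
tests).

Unspliced alignments attach to a spliced transcript only if their span
lies within one exon; terminal exons may extend outward, but only for
reads whose overhang is ≤ 25% of their span — a read mostly outside a
transcript is weak evidence of belonging to it (and, unchecked, antisense
reads would drag a gene's span across its partner).  Leftovers merge by
overlap into single-exon, unknown-strand transcripts.

Strand is inferred purely from junction consensus (all GT..AG forward →
'+', all CT..AC → '−', anything else unknown).  ESTGenes are connected
components of same-strand genomic overlap; unknown-strand transcripts
never bridge loci.

## Splice events and filters (`splice_events`)

Event definitions (between transcripts of one gene):

* CE/CSE — transcript B has one intron whose donor equals the donor of
  A's upstream flanking intron and whose acceptor equals the acceptor of
  A's downstream flanking intron, with ≥ 1 whole exon of A inside;
  exon_count is the stretch length.
* RI — B has an exon strictly covering A's intron on both sides.
* ALT5/ALT3 — two introns share exactly one coordinate; the differing
  side is interpreted in the gene's orientation.  A differing region that
  swallows a whole exon is a skipping difference, not an alternative
  site, and is suppressed.

Reliability filters (replacing the study's manual curation):
`canonical_sites` — every intron of every supporting alignment is in the
canonical set {GT:AG, GC:AG, AT:AC}, oriented by gene strand (the literal
variant {GT:AG, CG:AG, AT:AC} is available as a preset; CG:AG is most
likely a transposition of GC:AG, so the standard minor class is the
default and neither is asserted as intent); `indel_ok` — every indel run
outside introns is < 9 bases (exclusive); `flank_matches` — each event
boundary has ≥ 3 consecutive exactly matching aligned bases immediately
adjacent in at least one supporting alignment per aligned side (the far
side of a splice junction has no adjacent aligned bases and is not
demanded; a stricter all-alignments mode is available).  Events whose
support fails the filters are reported with their flags false, never
silently dropped.

## CE fraction, expectation and VE index (`splice_stats`)

`CE/(CE+RI)` at exon level under three CSE policies: every skipped exon
counted (`each_exon`), a stretch as one event (`stretch_as_one`), and
stretches excluded (`exclude_cse`); the policy ordering of the fraction
is monotone and tested as a property.  The linear expectation is
`0.84 × x`, x the fraction of introns > 200 b; the published "more than 2
standard errors" deviation claim needs the original cross-species
regression internals and is reported as not computable unless a standard
error is supplied.  Display rounding mirrors the study (2 or 3 decimals);
full precision is always retained.

## Antisense pairs (`antisense`)

Candidate pairs are overlapping (+,−) ESTGene spans where both members
carry ≥ 1 canonical GT-AG junction in their own orientation (guarding
against strand misassignment).  Containment is evaluated before
convergent/divergent, mirroring the study's separate tally of
fully-covering pairs; otherwise an overlap containing both 3′ termini is
convergent, else divergent.  Coding classification needs external CDS
spans (ORF calling is out of scope): pure-3′-UTR iff the overlap misses
both CDS and lies 3′ of each in that gene's orientation; missing CDS
gives the explicit class `undetermined`.

## Over-representation (`overrep`)

Expected per-library counts are proportional to library totals (the
natural exposure; the study does not state its expectation).  The
chi-square statistic uses Monte-Carlo multinomial replicates with
`p = (1 + #{stat_rep ≥ stat_obs}) / (B + 1)` and B = 200,000 so p < 1e-5
is attainable; a cheap screen (B = 2,000) runs first and the full B only
on genes that could reach the reporting threshold — genes failing the
screen cannot be flagged either way, so the two-pass scheme changes no
decision.  Strain bias uses the exact two-sided binomial test
(minimum-likelihood method, via `scipy.stats.binomtest`) with p0 = the
strain's share of mapped ESTs.  Flagging uses the study's raw 1e-5
threshold; a Benjamini–Hochberg column is reported but not used for
flagging.  The "well-supported" list is row-sum ≥ 50.

## Problem sizes used in the tests

The standard study is the generator default (100 genes, ≈ 4,700
noise-free reads); the artifact/cleaning study is a 40-gene, ≈ 1,400-read
run with substitutions (0.5% mid-read, end-ramped), indels (2 × 10⁻⁴),
vector remnants (15% of reads) and 2% contaminants.  Calibration uses
2,000 null genes at B = 2,000 and full-B confirmation only for planted
candidates.  These sizes were chosen to exercise every code path at desk
scale.

## Known limitations

* The aligner targets the low-divergence synthetic regime; it does not
  reproduce any external aligner's scoring and is not suitable for
  diverged or repeat-rich genomes.
* Terminal exon fragments shorter than 8 bases (or with ambiguous rescue
  placements) are left unaligned, so a small fraction of alignments carry
  a strict sub-chain of their read's true junctions.
* Greedy single-assignment support means EST-to-gene counts near isoform
  boundaries are deterministic but not unique in principle.
* Strand inference is junction-consensus only; single-exon loci always
  have unknown strand and are excluded from antisense pairing, as in the
  study's high-confidence SCP set.
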