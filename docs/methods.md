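# Methods

`repeatscape` implements the computational workflow of a low-coverage
whole-genome shotgun (WGS) survey of a very large, repeat-dominated
plant genome: given reference contigs (BAC-scale windows into the
genome) and a pool of short fixed-length reads at far below 1x
coverage, it characterizes the genome's repeat landscape — how much of
the sequence is repetitive at a given identity stringency, how many
genomic copies individual elements have, what the most common repeat
families look like, and how diverged the repeat complement is compared
with other genomes.  All estimators are exercised end-to-end on
synthetic genomes with planted ground truth.

## The statistical core

At genome-equivalent coverage `c = (total read bases) / (genome size)`
(the surveys of interest run at c ~ 0.015-0.04), a single-copy locus on
a contig receives Poisson-distributed alignment depth with mean `c`, so
it is almost always bare, while a locus with `C` genomic copies
receives mean depth `c * C`.  Three estimators follow directly:

* **Repetitive fraction.**  A contig position is classified repetitive
  when at least `min_depth = 2` read alignments cover it at the chosen
  identity stringency.  Under the single-copy null, P(depth >= 2) ~
  (cC)^2/2 ~ 6e-4 at c = 0.036, so false classification is negligible,
  while any locus with more than ~50 genome copies is detected with
  high probability.  Two stringencies are mapped (>= 75% and >= 99%
  nucleotide identity); because the strict hit set is a subset of the
  permissive one, strict depth is pointwise bounded by permissive
  depth, and the repetitive fraction is monotone in stringency.
* **Copy number.**  `copies = (mean depth over the element) / c`.  The
  relative standard error is `1/sqrt(n)` for `n` contributing reads, so
  a 4-kb element with 200 genomic copies at c = 0.036 (n ~ 480) is
  estimated to within ~14% at three standard errors.
* **Abundance (genome portion).**  For an element consensus, the
  fraction of pool reads with an alignment at >= 75% identity covering
  >= 90% of the read estimates the element family's fraction of the
  genome (binomial sampling of genomic positions).  Total base pairs,
  copy count (`total_bp / element_length`) and per-chromosome figures
  are arithmetic consequences given the configured genome size (22 Gb)
  and chromosome number (12).  The read-count rule slightly undercounts
  near element edges (a bias of order `read_length / element_length`)
  and the exact-motif telomere assay counts a read wholly when it
  contains one 7-bp motif copy; both biases are inherited deliberately
  from the published estimator and documented rather than corrected.

## Local alignment

Reads are aligned with +1/-1 match/mismatch and a linear gap cost of 2
per gap column (open = extend), i.e. a linear-gap Smith-Waterman.  The
production engine seeds on exact words (11-mers at >= 90% identity
targets, 8-mers below) and runs the full dynamic program on merged
candidate windows (numba-compiled).  Locally optimal non-overlapping
hits are enumerated best-first with segment splitting; overlapping hits
of one read across strands collapse to the best-scoring one, ties
breaking by smallest contig end, then read end, then + strand.

Two stringency interfaces exist because the published score/identity
pairing is internally inconsistent (score 55 on a 60-bp read implies
96.7% identity, not 99%; score 24 implies 70%, not 75%): identity mode
(default; 0.75/0.99) and raw score-threshold mode (24/55).  In identity
mode, enumeration also applies a significance floor of score 24 — the
published permissive threshold — because weaker gapped local alignments
(score ~15 over ~30 columns) occur at a high rate between unrelated
sequences and would contaminate the 70-84% identity bin.

A pure-numpy Smith-Waterman over the whole contig (`sw_oracle`) is an
independently written second route used in tests.  Seeding sensitivity:
an exact k-mer is pigeonhole-guaranteed for a full-length hit with at
most `floor(L/k) - 1` mismatches; beyond that, misses are possible for
adversarially spaced mismatches.  The oracle-equivalence tests
therefore use hit-bearing instances with <= 3 substitutions or one
indel per 40-bp read, where agreement must be exact.

## Synthetic genomes

The generator emulates the repeat architecture such a survey infers: a
few young, nearly identical LTR-retroelement-like families over a
dominant background of ancient (20-30% diverged), heavily fragmented
and occasionally nested elements; tandem minisatellite arrays including
a 50-bp centromere-like unit; perfect telomeric TTTAGGG arrays;
low-complexity tracts; and compact multi-exon genes with a 5:1
pseudogene excess.  Base composition defaults to A/C/G/T =
0.30/0.20/0.20/0.30, matching the surveyed genome's measured
composition.

Divergence is substitution-only by default: each copy is the family
consensus mutated independently per base, so the ledger's per-copy
identity is exact and the estimators' identity thresholds translate
directly into expected recovery.  A family's `divergence` d is
copy-to-consensus; two copies of the family differ at rate
`2d(1-d) + (2/3)d^2` (~2d for small d), which matters when choosing
conditions for identity-binned tests: "repeats 20% diverged from each
other" means d ~ 0.105.

Dispersed copies are placed by the insertion model (background split at
uniformly drawn points), so planted features never overlap except
through explicit nesting, which splits the host copy into two ledger
fragments.  LTR families carry identical-at-birth terminal repeats that
diverge independently per copy.  Reads are sampled uniformly from both
strands with independent substitution errors; N bases never occur in
simulated data.  Everything is deterministic per seed.

What the generator does *not* emulate: indels within copies (an
optional rate exists conceptually but the estimators are
substitution-framed and it defaults off), transposition dynamics over
time, GC heterogeneity along the genome, sequencing-quality profiles,
and chimeric reads.  Passing tests therefore demonstrate estimator
correctness under substitution divergence and uniform sampling, not
robustness to real-platform artifacts.

## Permissive consensus assembly

At c << 1 no two reads are expected to sample the same genomic locus,
but an abundant family is sampled hundreds of times across its copies;
stacking those reads yields the family consensus ("most common base at
each position").  The assembler:

1. seeds on the most frequent canonical 16-mer passing a
   base-composition entropy filter (>= 1.5 bits), ties lexicographic;
2. grows the consensus greedily in both directions, recruiting reads
   (either strand, discovered through an exact 8-mer index) that
   overlap the current end by >= 20 columns at >= 80% identity — or by
   >= 14 near-perfect columns, a rescue needed because the frontier
   only sees reads anchored *before* a new column, a thinned sample of
   true column depth; a bare exact 8-mer anchor would admit ~`N/4^8`
   random voters per column and is not accepted;
3. sets each new column to the majority base (ties break toward the
   pool-wide commoner base, then alphabetically), extending while any
   voter exists; the configured `min_column_depth` (default 5) is
   enforced on the final support profile by trimming unsupported
   terminal columns, which also prunes the short walk-offs past element
   boundaries where per-copy flanks disagree;
4. stops on a wrap: every new consensus 16-mer is registered, and a
   k-mer recurring at lag >= 5 with matching preceding context means
   the walk has re-entered sequence it already produced.  A short lag
   (<= 200) is a tandem unit, reported as `tandem_period` and
   re-represented as the unit tiled past one unit plus a read length so
   junction-spanning reads can be recruited and quantified; a long lag
   is the signature of circling a terminal-repeat-bounded element
   (interior -> LTR -> interior), so the product is the element
   interior plus one terminal repeat — the same "with one LTR"
   convention the original survey reported, and the reason an
   element planted at 4.2 kb with 300-bp LTRs assembles to ~3.9 kb;
5. iterates seed -> extend -> subtract matching reads, ranking elements
   by supporting-read count.

Problem sizes used in the recovery tests: consensus recovery uses 500
copies of a 4.2-kb family at 5% divergence with 0.03x 40-bp reads
(frontier voter intensity ~8 per column); the three-family ranking run
uses a 10-Mb genome with families at ~1.6%/1.3%/0.3% and a 0.6x pool,
chosen so the per-column voter intensity (~10-13) supports full-length
assembly of the two dispersed families.  At 0.036x and 38 copies the
voter intensity is ~1 and no assembler of this design can walk 4 kb;
the published full-scale pool (21M reads over a 22-Gb genome, ~3000x
column depth on its top families) is far above that regime.

## Identity-binned divergence profiles

To compare genomes by repeat age, a genome-equivalent pool of 60-bp
reads (0.036x) is aligned at >= 70% identity to a fixed number of bases
of uniformly sampled, non-overlapping 10-kb regions; each region
position is attributed to the identity bin (70-84 / 85-97 / 98-100%) of
its best covering alignment, with covered base pairs (not alignment
counts) as the measure so genomes of different sizes share a
denominator.  Sampling is replicated (default 10x) and averaged.  Two
features of the statistic matter for interpretation: every genome shows
a top-bin floor of ~`1 - exp(-c)` (~3.5%) from reads re-aligning to
their own source locus, and the best-of-covering-reads identity rises
with coverage-per-family, so the per-position bin reflects the nearest
sampled relative, not the mean pairwise divergence.  Bin boundaries on
the identity fraction are [0.70, 0.85), [0.85, 0.98), [0.98, 1.0].

## Contig-level feature discovery

* **Direct-repeat pairs** (candidate LTRs): exact-11-mer self-seeding
  off the main diagonal, then maximal-scoring gapless segment extension
  (+1/-1).  A pair is reported when the segment is >= 100 bp, its
  footprints span >= 500 bp, identity >= 0.50, and score >= 24.  The
  score floor makes false pairs on 100-kb random contigs vanishingly
  rare (a +24 excursion against a -0.5/column drift), at the cost of
  the weakest real pairs (~53% identity), which exact-word seeding
  cannot find anyway; recall is >= 90% for pairs up to 20% mutual
  divergence with >= 100-bp repeats.  Maximal segments may absorb a few
  matching flank bases, so reported boundaries are approximate to
  within a few positions.
* **Tandem arrays**: for each period p in 5-200 bp, lag-p self-matches
  are smoothed over 2p and runs at >= 80% match merged (gaps under one
  period bridged); arrays need >= 2 unit copies and a +1/-1 score of at
  least 24 across the array.  The smallest qualifying period is
  reported; multiples and mono-base runs (delegated to the
  simple-repeat detector) are suppressed.  This is an original
  lag-correlation detector honoring the published unit-size bounds, not
  a reimplementation of tandem-repeat-finder scoring.
* **Simple repeats**: 64-bp windows with base-composition entropy
  below 1.0 bits, plus perfect 1-4-bp unit runs of >= 10/6/5/5 copies.
  The mono-nucleotide floor is 10 copies rather than 8 because an 8-bp
  homopolymer occurs by chance ~0.6 times per 10 kb of random sequence,
  which would violate the expectation of zero calls on random input.
* **ORF elements**: ATG-to-stop spans >= 240 bp in all six frames,
  dropped when overlapping annotated genes/exons, reduced to the
  longest per overlapping cluster, and optionally flagged when >= 50%
  of the span lies in repetitive (depth >= 2) coverage.  "Putatively
  noncoding" is operationalized as non-overlap with the supplied
  annotation; with no annotation, all sequence is eligible.

## Numerical and interface choices

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
inclusive) and `.sgr` (1-based dense) convert at the I/O boundary.
`.sgr` positions are fixed as 1-based.  One integer seed drives every
stage; module-level generators derive from it deterministically, and
identical seeds give byte-identical outputs.  Presentation rounding
(portions to 2-3 significant figures, copies and base pairs to 2)
applies only to report tables; raw values are always retained.
Degenerate inputs fail loudly with named exceptions (duplicate FASTA
ids, mixed read lengths, empty pools, zero-coverage copy-number
requests, out-of-bounds hits).

## Known limitations

* The aligner supports linear gap costs only (open = extend = 2), which
  is the published scheme; distinct open/extend penalties are out of
  scope.
* Abundance and coverage estimators assume substitution-style
  divergence; indel-rich families would shift alignment identity and
  lower recovery (the estimators degrade monotonically as family
  divergence exceeds `1 - min_identity`).
* The assembler's consensus for a tandem family is a rotation of the
  true unit (phase is set by the seed), and for an LTR element it is
  the interior plus one terminal repeat; neither is the full planted
  element verbatim.
* A genuine long internal duplication (> ~46 bp of exact repeat with
  matching context) inside a dispersed element would trigger the wrap
  guard early; the synthetic families are random-sequence-derived and
  do not exhibit this.
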