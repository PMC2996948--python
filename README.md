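# repeatscape

Repeat-landscape profiling of very large plant genomes from
low-coverage whole-genome shotgun (WGS) reads.

Conifer genomes (20-40 Gb) are dominated by repetitive elements, yet at
survey-scale sequencing depths (0.015-0.04 genome equivalents) almost
no locus is sampled twice.  `repeatscape` is built for exactly this
regime.  It provides, as a library and a CLI, the full analysis chain
such a survey needs:

* **synthetic genomes with planted ground truth** — dispersed LTR
  retroelement families at chosen copy numbers and divergences (young
  near-identical vs ancient 20-30% diverged, with fragmentation and
  nesting), tandem and telomeric (TTTAGGG) arrays, low-complexity
  tracts, compact genes and pseudogenes — plus uniformly sampled
  fixed-length read pools with per-feature ledgers to score every
  estimator against;
* **identity-thresholded coverage maps**: reads aligned to reference
  contigs under +1/-1 scoring with linear gap cost 2 at two
  stringencies (>= 75% and >= 99% identity), written as dense 1-based
  `.sgr` depth tracks;
* **repetitive-fraction and copy-number estimation**: a position with
  depth >= 2 is repetitive (P ~ 6e-4 under the single-copy null at
  0.036x); an element's copy number is its mean depth divided by the
  pool's genome-equivalent coverage;
* **abundance estimation**: an element's genome portion is the
  fraction of pool reads aligning to its consensus at >= 75% identity
  over >= 90% of the read; total bp, copies and per-chromosome figures
  follow from the genome size (22 Gb) and chromosome count (12);
  an exact-motif assay quantifies telomeric repeat content;
* **permissive consensus assembly**: reconstructs the genome's most
  common repeat family consensi directly from the unassembled pool by
  greedy majority-rule extension from the most frequent k-mer, with
  tandem-period and LTR-pair structure detection;
* **contig-level repeat feature discovery**: direct-repeat pairs
  (candidate LTRs, >= 100 bp repeats spanning >= 500 bp), tandem arrays
  (5-200 bp units), simple/low-complexity repeats, and long (>= 240 bp)
  nongenic ORF elements;
* **identity-binned divergence profiles**: genome-equivalent 60-bp
  pools aligned to sampled regions, positions binned at 70-84 / 85-97 /
  98-100% identity over 10 replicates — the procedure that separates
  old-repeat genomes (pine-like) from young-repeat genomes
  (maize-like).

`docs/methods.md` describes the models, parameter choices and known
limitations in detail.

## Worked example

Abundance arithmetic from a real survey's printed inputs — 330,219 of
21 million WGS reads matching a 4.2-kb copia-like consensus in a 22-Gb,
12-chromosome genome:

```python
from repeatscape.abundance import AbundanceEstimate, round_sig
from repeatscape.config import AnalysisConfig

cfg = AnalysisConfig()  # 22-Gb genome, 12 chromosomes
est = AbundanceEstimate("copia-like", 330_219, 21_000_000, 4200,
                        cfg.genome_size_bp, cfg.n_chromosomes)
print(round_sig(100 * est.genome_portion, 3))  # 1.57   (% of genome)
print(round_sig(est.total_bp, 2))              # 350000000.0  (bp)
print(round_sig(est.copies, 2))                # 82000.0  (genomic copies)
```

The element occupies 1.57% of the genome — about 350 Mb, or 82,000
full-length copies.

End-to-end on synthetic data with planted truth:

```python
from repeatscape import simulate, assemble
from repeatscape.simulate import GenomeSpec, ReadSimSpec, RepeatFamilySpec

spec = GenomeSpec(
    genome_length_bp=6_000_000,
    families=[RepeatFamilySpec("fam", 4200, 500, divergence=0.05,
                               ltr_length_bp=300)],
    seed=11,
)
truth = simulate.simulate_genome(spec)
reads = simulate.simulate_reads(truth, ReadSimSpec(40, 0.03, 0.01, seed=12))
params = assemble.AssemblyParams()
cons = assemble.extend_consensus(reads, assemble.select_seed(reads, params), params)
print(len(cons), cons.supporting_read_count)   # 3923 1608
```

From 4,500 reads at 0.03x coverage the assembler reconstructs a
3,923-bp consensus (the element interior plus one terminal repeat —
the walk wraps at the second LTR) supported by 1,608 reads, over 99%
identical to the planted family consensus.

The same stages are available from the shell:

```bash
repeatscape simulate --seed 1 --genome-size 2000000 --out run/sim
repeatscape coverage --reads run/sim/reads.fasta \
    --contigs run/sim/genome.fasta --out run/cov
repeatscape assemble --reads run/sim/reads.fasta --out run/asm
repeatscape features --contigs run/sim/genome.fasta \
    --annotations run/sim/truth.gff3 --out run/feat
```

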