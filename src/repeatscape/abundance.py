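"""Read-count abundance estimators for repeat elements.

An element's genome portion is the fraction of a WGS read pool that
aligns to it; with uniformly sampled reads this is an unbiased estimate
of the fraction of genomic bases belonging to the family (up to edge
effects of one read length per element copy).  Total base pairs, copy
number and per-chromosome figures follow arithmetically from the genome
size and chromosome count.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _seq
from .align import ContigIndex, find_hits
from .config import AnalysisConfig
from .seqio import ReadSet


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (presentation helper)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass
class AbundanceEstimate:
    element_name: str
    n_matching_reads: int
    pool_size: int
    element_length_bp: int
    genome_size_bp: int
    n_chromosomes: int

    def __post_init__(self) -> None:
        if self.pool_size <= 0:
            raise ValueError("empty read pool")
        if not (0 <= self.n_matching_reads <= self.pool_size):
            raise ValueError("matching reads outside [0, pool size]")

    @property
    def genome_portion(self) -> float:
        return self.n_matching_reads / self.pool_size

    @property
    def total_bp(self) -> float:
        return self.genome_portion * self.genome_size_bp

    @property
    def copies(self) -> float:
        return self.total_bp / self.element_length_bp

    @property
    def per_chromosome_copies(self) -> float:
        return self.copies / self.n_chromosomes

    @property
    def per_chromosome_bp(self) -> float:
        return self.total_bp / self.n_chromosomes

    def as_row(self) -> dict:
        """Printed-precision row (portions 3 sf, bp and copies 2 sf)."""
        return {
            "element": self.element_name,
            "n_reads": self.n_matching_reads,
            "pool_size": self.pool_size,
            "genome_portion_pct": round_sig(100 * self.genome_portion, 3),
            "total_bp": round_sig(self.total_bp, 2),
            "element_length_bp": self.element_length_bp,
            "copies": round_sig(self.copies, 2),
            "per_chromosome_copies": round_sig(self.per_chromosome_copies, 2),
            "per_chromosome_bp": round_sig(self.per_chromosome_bp, 2),
        }


def genome_equivalents(total_read_bases: float, genome_size: float) -> float:
    """Genome-equivalent coverage = total read bases / genome size."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if total_read_bases < 0:
        raise ValueError("total read bases must be non-negative")
    return total_read_bases / genome_size


def genome_fraction(bp: float, config: AnalysisConfig) -> float:
    """Percentage of the configured genome represented by ``bp`` bases."""
    if bp < 0:
        raise ValueError("bp must be non-negative")
    return 100.0 * bp / config.genome_size_bp


def count_matching_reads(
    reads: ReadSet,
    consensus,
    min_identity: float = 0.75,
    min_read_coverage: float = 0.9,
    base_weighted: bool = False,
) -> float:
    """Reads with an alignment to ``consensus`` covering >= 90% of the read.

    The default read-count rule mirrors the published accounting (a read
    either matches or it does not); ``base_weighted=True`` instead sums
    aligned read fractions, which is statistically cleaner near element
    edges.
    """
    index = consensus if isinstance(consensus, ContigIndex) else ContigIndex(consensus)
    L = reads.read_length
    need = min_read_coverage * L
    total = 0.0
    for i in range(reads.count):
        hits = find_hits(
            reads.codes[i],
            index,
            min_identity=min_identity,
            min_aln_len=int(math.ceil(need)),
        )
        spans = [h.read_end - h.read_start for h in hits]
        if not spans:
            continue
        if base_weighted:
            total += min(1.0, max(spans) / L)
        elif max(spans) >= need:
            total += 1
    return total


def quantify_element(
    reads: ReadSet,
    consensus,
    config: AnalysisConfig,
    element_name: str = "element",
    min_identity: float = 0.75,
    element_length_bp: Optional[int] = None,
) -> AbundanceEstimate:
    """Full abundance record for one element consensus."""
    if reads.count == 0:
        raise ValueError("empty read pool")
    seq = consensus.sequence if hasattr(consensus, "sequence") else consensus
    if isinstance(seq, str) and len(seq) < reads.read_length:
        raise ValueError("consensus shorter than the read length")
    n = int(count_matching_reads(reads, seq, min_identity=min_identity))
    return AbundanceEstimate(
        element_name=element_name,
        n_matching_reads=n,
        pool_size=reads.count,
        element_length_bp=element_length_bp or len(seq),
        genome_size_bp=config.genome_size_bp,
        n_chromosomes=config.n_chromosomes,
    )


def motif_assay(
    reads: ReadSet,
    config: AnalysisConfig,
    motif: str = "TTTAGGG",
    element_name: str = "tel-rpt",
) -> AbundanceEstimate:
    """Exact-motif occurrence assay (telomeric repeat content).

    A read matches if it contains the motif or its reverse complement at
    least once; multiplicity within a read does not add.  The implied
    total-bp figure inherits the acknowledged upward bias that a read
    containing one motif copy is counted wholly.
    """
    if not motif:
        raise ValueError("empty motif")
    m = _seq.encode(motif)
    if m.shape[0] > reads.read_length:
        raise ValueError("motif longer than the read length")
    matched = np.zeros(reads.count, dtype=bool)
    for probe in (m, _seq.revcomp(m)):
        k = probe.shape[0]
        w = reads.codes.shape[1] - k + 1
        hit = np.ones((reads.count, w), dtype=bool)
        for t in range(k):
            hit &= reads.codes[:, t : t + w] == probe[t]
        matched |= hit.any(axis=1)
    return AbundanceEstimate(
        element_name=element_name,
        n_matching_reads=int(matched.sum()),
        pool_size=reads.count,
        element_length_bp=len(motif),
        genome_size_bp=config.genome_size_bp,
        n_chromosomes=config.n_chromosomes,
    )


def motif_read_hit_rate(genome_codes: np.ndarray, motif: str, read_length: int) -> float:
    """Exact expected fraction of error-free reads containing the motif.

    Brute-force enumeration over every read window of the genome (both
    read orientations contain the motif iff the forward window contains
    the motif or its reverse complement), used as the oracle for
    ``motif_assay`` on synthetic genomes.
    """
    m = _seq.encode(motif)
    n = genome_codes.shape[0]
    starts = n - m.shape[0] + 1
    occ = np.ones(starts, dtype=bool)
    occ_rc = np.ones(starts, dtype=bool)
    rc = _seq.revcomp(m)
    for t in range(m.shape[0]):
        occ &= genome_codes[t : t + starts] == m[t]
        occ_rc &= genome_codes[t : t + starts] == rc[t]
    any_occ = occ | occ_rc
    # a read window [s, s+L) contains a motif occurrence starting at p
    # iff s <= p <= s + L - |m|
    w = read_length - m.shape[0] + 1
    cum = np.concatenate(([0], np.cumsum(any_occ)))
    n_windows = n - read_length + 1
    has = cum[np.arange(n_windows) + w] - cum[np.arange(n_windows)]
    return float(np.count_nonzero(has > 0)) / n_windows


def gc_content(seq_or_reads) -> dict[str, float]:
    """Base fractions over non-N positions plus the combined GC fraction."""
    if isinstance(seq_or_reads, ReadSet):
        codes = seq_or_reads.codes.ravel()
    elif isinstance(seq_or_reads, str):
        codes = _seq.encode(seq_or_reads)
    else:
        codes = np.asarray(seq_or_reads)
    counts = np.bincount(codes[codes < 4], minlength=4).astype(float)
    tot = counts.sum()
    if tot == 0:
        raise ValueError("no unambiguous bases")
    frac = counts / tot
    return {
        "A": float(frac[0]),
        "C": float(frac[1]),
        "G": float(frac[2]),
        "T": float(frac[3]),
        "GC": float(frac[1] + frac[2]),
    }


def table3_report(estimates: list[AbundanceEstimate]) -> pd.DataFrame:
    """One row per element with all abundance fields at printed precision."""
    return pd.DataFrame([e.as_row() for e in estimates])
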