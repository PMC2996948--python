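"""Identity-binned repeat-divergence profiles of a genome.

The procedure compares genomes by how diverged their repeats are: draw a
genome-equivalent pool of 60-bp reads, sample a fixed number of bases of
reference regions, align the pool to the regions at a permissive
identity floor, and attribute every region position to the identity bin
of its best covering alignment (young repeats pile up at 98-100%
identity, ancient ones at 70-84%).  The sampling is replicated and
averaged.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _seq
from .align import ContigIndex, find_hits
from .seqio import Interval, ReadSet
from .simulate import GenomeTruth, ReadSimSpec, simulate_reads

DEFAULT_BINS = ((0.70, 0.84), (0.85, 0.97), (0.98, 1.00))


@dataclass
class DivergenceConfig:
    read_length: int = 60
    coverage: float = 0.036
    region_total_bp: int = 920_000
    region_piece_bp: int = 10_000
    bins: tuple = DEFAULT_BINS
    replicates: int = 10
    min_identity: float = 0.70
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo = 0.0
        for b0, b1 in self.bins:
            if not (lo <= b0 <= b1 <= 1.0):
                raise ValueError("bins must be disjoint, ordered and within (0, 1]")
            lo = b1


@dataclass
class IdentityBinProfile:
    """Per-bin mean fraction of sampled positions, with replicate detail."""

    bin_edges: tuple
    per_replicate: np.ndarray  # (replicates, n_bins + 1); last col = unaligned

    @property
    def mean(self) -> np.ndarray:
        return self.per_replicate.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.per_replicate.std(axis=0, ddof=1 if self.per_replicate.shape[0] > 1 else 0)

    def to_frame(self, label: str = "genome") -> pd.DataFrame:
        names = [f"{int(100 * b0)}-{int(100 * b1)}%" for b0, b1 in self.bin_edges]
        names.append("unaligned")
        return pd.DataFrame(
            {
                "genome": label,
                "bin": names,
                "mean_fraction": self.mean,
                "sd": self.sd,
            }
        )


def sample_regions(
    genome_length: int,
    total_bp: int,
    rng: np.random.Generator,
    piece_bp: int = 10_000,
) -> list[Interval]:
    """Non-overlapping uniformly placed pieces totaling exactly total_bp."""
    if total_bp > genome_length:
        raise ValueError("cannot sample more bases than the genome holds")
    if total_bp == genome_length:
        return [Interval("g", 0, genome_length, label="region")]
    sizes = [piece_bp] * (total_bp // piece_bp)
    rem = total_bp % piece_bp
    if rem:
        sizes.append(rem)
    slack = genome_length - total_bp
    cuts = np.sort(rng.integers(0, slack + 1, size=len(sizes)))
    out = []
    consumed = 0
    for size, cut in zip(sizes, cuts):
        start = int(cut) + consumed
        out.append(Interval("g", start, start + size, label="region"))
        consumed += size
    return out


def chop_reads(sequences: Sequence[str], length: int = 60) -> ReadSet:
    """Non-overlapping consecutive fixed-length reads; remainders dropped."""
    seqs = []
    for s in sequences:
        for i in range(0, len(s) - length + 1, length):
            seqs.append(s[i : i + length])
    if not seqs:
        raise ValueError("no sequence long enough to chop")
    return ReadSet.from_strings(seqs)


def _bin_index(identity: float, bins) -> Optional[int]:
    for i, (b0, b1) in enumerate(bins):
        nxt = bins[i + 1][0] if i + 1 < len(bins) else 1.01
        if b0 <= identity < nxt:
            return i
    return None


def profile_divergence(
    truth: GenomeTruth,
    config: DivergenceConfig,
    reads: Optional[ReadSet] = None,
) -> IdentityBinProfile:
    """Replicated identity-binned coverage of randomly sampled regions.

    Per replicate: a fresh read pool at ``coverage`` equivalents (unless
    a fixed pool is supplied), fresh sampled regions, and per-position
    attribution to the identity bin of the best covering alignment.
    """
    rng = np.random.default_rng(config.seed)
    nb = len(config.bins)
    rows = np.zeros((config.replicates, nb + 1))
    genome = truth.codes
    for rep in range(config.replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        if reads is None:
            pool = simulate_reads(
                truth,
                ReadSimSpec(
                    read_length_bp=config.read_length,
                    coverage=config.coverage,
                    error_rate=config.error_rate,
                    seed=rep_seed,
                ),
            )
        else:
            pool = reads
        regions = sample_regions(
            truth.genome_length,
            config.region_total_bp,
            np.random.default_rng(rep_seed + 1),
            config.region_piece_bp,
        )
        bin_bp = np.zeros(nb + 1)
        total_bp = 0
        for region in regions:
            seg = genome[region.start : region.end]
            index = ContigIndex(seg, f"region_{region.start}")
            best = np.zeros(seg.shape[0])  # best covering identity per position
            for i in range(pool.count):
                for h in find_hits(
                    pool.codes[i],
                    index,
                    min_identity=config.min_identity,
                ):
                    np.maximum(
                        best[h.contig_start : h.contig_end],
                        h.identity,
                        out=best[h.contig_start : h.contig_end],
                    )
            total_bp += seg.shape[0]
            aligned = best >= config.min_identity
            bin_bp[nb] += np.count_nonzero(~aligned)
            for i in range(nb):
                lo = config.bins[i][0]
                hi = config.bins[i + 1][0] if i + 1 < nb else 1.01
                bin_bp[i] += np.count_nonzero(aligned & (best >= lo) & (best < hi))
        rows[rep] = bin_bp / total_bp
    return IdentityBinProfile(config.bins, rows)


def compare_genomes(
    genomes: dict[str, GenomeTruth],
    config: DivergenceConfig,
) -> pd.DataFrame:
    """Profile several genomes under one configuration; long-form table."""
    frames = []
    for label, truth in genomes.items():
        prof = profile_divergence(truth, config)
        frames.append(prof.to_frame(label))
    return pd.concat(frames, ignore_index=True)
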