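"""Per-base coverage maps and depth-ratio copy-number estimation.

Depth at a position counts overlapping read alignments ("hits per base
pair"), so a read aligning twice to a contig contributes twice.  Copy
number of an element is its mean depth divided by the genome-equivalent
coverage of the read pool: at 0.036x coverage a single-copy locus has
expected depth 0.036, an element with C genomic copies expected depth
0.036 * C.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import AlignmentHit
from .seqio import Interval


@dataclass
class CoverageMap:
    contig_id: str
    threshold: float
    depth: np.ndarray
    genome_coverage: float

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError("depth must be non-negative")

    def __len__(self) -> int:
        return int(self.depth.shape[0])


@dataclass
class CopyNumberEstimate:
    interval: Interval
    mean_depth: float
    genome_coverage: float

    @property
    def copies(self) -> float:
        return self.mean_depth / self.genome_coverage


def build_coverage_map(
    hits: list[AlignmentHit],
    contig_length: int,
    contig_id: str,
    threshold: float,
    genome_coverage: float,
) -> CoverageMap:
    """depth[p] = number of hits whose [start, end) contains p."""
    diff = np.zeros(contig_length + 1, dtype=np.int64)
    for h in hits:
        if h.contig_start < 0 or h.contig_end > contig_length:
            raise ValueError(
                f"hit [{h.contig_start}, {h.contig_end}) outside contig of "
                f"length {contig_length}"
            )
        diff[h.contig_start] += 1
        diff[h.contig_end] -= 1
    depth = np.cumsum(diff[:-1])
    return CoverageMap(contig_id, threshold, depth, genome_coverage)


def repetitive_fraction(covmap: CoverageMap, min_depth: int = 2) -> float:
    """Fraction of positions with at least ``min_depth`` overlapping hits.

    At far-below-1x coverage a single-copy position almost never carries
    two independent alignments, so depth >= 2 flags multi-copy sequence.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if len(covmap) == 0:
        return 0.0
    return float(np.count_nonzero(covmap.depth >= min_depth)) / len(covmap)


def copy_number(covmap: CoverageMap, interval: Interval) -> CopyNumberEstimate:
    if interval.end > len(covmap):
        raise ValueError("interval outside contig")
    if len(interval) == 0:
        raise ValueError("zero-length interval")
    if covmap.genome_coverage <= 0:
        raise ValueError("copy number undefined at zero genome coverage")
    mean_depth = float(covmap.depth[interval.start : interval.end].mean())
    return CopyNumberEstimate(interval, mean_depth, covmap.genome_coverage)


def window_profile(covmap: CoverageMap, window: int = 50) -> pd.DataFrame:
    """Mean depth in consecutive windows; the last window may be short."""
    if window < 1:
        raise ValueError("window must be >= 1")
    L = len(covmap)
    starts = np.arange(0, L, window)
    ends = np.minimum(starts + window, L)
    cum = np.concatenate(([0], np.cumsum(covmap.depth)))
    means = (cum[ends] - cum[starts]) / (ends - starts)
    return pd.DataFrame(
        {"contig_id": covmap.contig_id, "start": starts, "end": ends, "mean_depth": means}
    )


def repetitive_segments(covmap: CoverageMap, min_depth: int = 2) -> list[Interval]:
    """Maximal runs of repetitive positions, for BED export."""
    mask = covmap.depth >= min_depth
    if not mask.any():
        return []
    edges = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(covmap))
    return [
        Interval(covmap.contig_id, int(s), int(e), label="repetitive")
        for s, e in zip(starts, ends)
    ]
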