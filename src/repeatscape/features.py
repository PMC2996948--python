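"""Contig-level discovery of repeat features.

Four detectors operating on a single contig:

* direct-repeat pairs (candidate LTRs): maximal gapless self-alignments
  of >= 100 bp spanning >= 500 bp, found by exact-word seeding plus
  best-segment extension under +1/-1 scoring;
* tandem arrays of 5-200 bp units via lag correlation;
* simple / low-complexity repeats via windowed entropy and short perfect
  unit runs;
* long nongenic open reading frames (>= 240 bp) as signatures of
  unclassified coding-capable repeats.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from intervaltree import IntervalTree

from . import _seq
from .coverage import CoverageMap
from .seqio import Interval

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class DirectRepeatPair:
    first: Interval
    second: Interval
    identity: float

    @property
    def span_bp(self) -> int:
        return self.second.end - self.first.start


@dataclass
class TandemArray:
    interval: Interval
    period_bp: int
    copy_number: float
    consensus_unit: str
    percent_matches: float


@dataclass
class OrfElement:
    interval: Interval
    frame: int
    overlaps_repetitive_coverage: Optional[bool] = None

    @property
    def length_bp(self) -> int:
        return len(self.interval)


# ---------------------------------------------------------------------------
# direct repeats


def _best_segment(match: np.ndarray) -> tuple[int, int, int]:
    """Maximal-scoring run under +1 match / -1 mismatch (Kadane).

    Returns (start, end, score) of the best segment of the boolean
    match vector.
    """
    contrib = np.where(match, 1, -1)
    cum = np.concatenate(([0], np.cumsum(contrib)))
    run_min = np.minimum.accumulate(cum[:-1])
    argmin = np.zeros(len(cum) - 1, dtype=np.int64)
    best_idx = 0
    for i in range(1, len(cum) - 1):  # positions of running minima
        if cum[i] < cum[best_idx]:
            best_idx = i
        argmin[i] = best_idx
    scores = cum[1:] - run_min
    end = int(np.argmax(scores)) + 1
    start = int(argmin[end - 1])
    return start, end, int(scores[end - 1])


def find_direct_repeats(
    contig: str,
    min_len: int = 100,
    min_span: int = 500,
    min_identity: float = 0.50,
    annotations: Optional[list[Interval]] = None,
    contig_id: str = "contig",
    word_size: int = 11,
    min_score: int = 24,
) -> list[DirectRepeatPair]:
    """Same-strand direct-repeat pairs within one contig.

    Self-comparison seeded on exact ``word_size``-mers off the main
    diagonal; each seeded diagonal is extended to its maximal-scoring
    gapless segment.  A segment of length >= ``min_len`` whose two
    footprints span >= ``min_span`` is reported as a candidate LTR pair.
    When annotations are supplied, pairs with either repeat overlapping
    an exon are dropped (putatively noncoding only).
    """
    codes = _seq.encode(contig)
    n = codes.shape[0]
    if n < min_span:
        return []
    vals, valid = _seq.kmer_ints(codes, word_size)
    order = np.argsort(vals, kind="stable")
    sorted_vals = vals[order]
    # group seed positions by k-mer value; pair positions on each diagonal
    diag_seeds: dict[int, list[int]] = {}
    boundaries = np.nonzero(np.diff(sorted_vals))[0] + 1
    groups = np.split(order, boundaries)
    for grp in groups:
        grp = grp[valid[grp]]
        if grp.shape[0] < 2 or grp.shape[0] > 50:
            continue
        pos = np.sort(grp)
        for i in range(pos.shape[0]):
            for j in range(i + 1, pos.shape[0]):
                d = int(pos[j] - pos[i])
                if d >= word_size:
                    diag_seeds.setdefault(d, []).append(int(pos[i]))
    exon_tree = None
    if annotations is not None:
        exon_tree = IntervalTree()
        for iv in annotations:
            if iv.label in ("exon", "gene", "CDS") and iv.contig_id == contig_id:
                exon_tree[iv.start : iv.end] = iv.label
    pairs: list[DirectRepeatPair] = []
    claimed: list[tuple[int, int, int, int]] = []
    for d, seeds in sorted(diag_seeds.items()):
        seeds = sorted(set(seeds))
        # cluster seeds on the diagonal, one extension window per cluster
        clusters: list[list[int]] = [[seeds[0]]]
        for s in seeds[1:]:
            if s - clusters[-1][-1] <= 2000:
                clusters[-1].append(s)
            else:
                clusters.append([s])
        for cl in clusters:
            lo = max(0, cl[0] - 3000)
            hi = min(n - d, cl[-1] + word_size + 3000)
            if hi - lo < min_len:
                continue
            match = codes[lo:hi] == codes[lo + d : hi + d]
            s, e, score = _best_segment(match)
            seg_len = e - s
            ident = float(np.count_nonzero(match[s:e])) / seg_len
            if seg_len < min_len or score < min_score or ident < min_identity:
                continue
            a_start, a_end = lo + s, lo + e
            b_start, b_end = a_start + d, a_end + d
            if b_end - a_start < min_span:
                continue
            key = (a_start, a_end, b_start, b_end)
            if any(
                abs(key[0] - c[0]) < min_len // 2 and abs(key[2] - c[2]) < min_len // 2
                for c in claimed
            ):
                continue
            first = Interval(contig_id, a_start, a_end, "+", "direct_repeat")
            second = Interval(contig_id, b_start, b_end, "+", "direct_repeat")
            if exon_tree is not None and (
                exon_tree.overlap(a_start, a_end) or exon_tree.overlap(b_start, b_end)
            ):
                continue
            claimed.append(key)
            pairs.append(DirectRepeatPair(first, second, round(ident, 4)))
    pairs.sort(key=lambda p: (p.first.start, p.second.start))
    return pairs


# ---------------------------------------------------------------------------
# tandem repeats


def find_tandem_repeats(
    contig: str,
    period_range: tuple[int, int] = (5, 200),
    min_copies: float = 2.0,
    min_fraction_match: float = 0.8,
    contig_id: str = "contig",
) -> list[TandemArray]:
    """Tandem arrays by lag correlation, smallest period first.

    For each candidate period p the lag-p self-match profile is smoothed
    over one period; runs where the smoothed match fraction stays at or
    above ``min_fraction_match`` and that hold >= ``min_copies`` unit
    copies become arrays.  An array already explained by a smaller
    period is not re-reported at its multiples, and single-base runs are
    left to the simple-repeat detector.
    """
    codes = _seq.encode(contig)
    n = codes.shape[0]
    out: list[TandemArray] = []
    covered = IntervalTree()
    for p in range(period_range[0], period_range[1] + 1):
        if n < p * 2:
            break
        match = (codes[:-p] == codes[p:]).astype(np.float64)
        kernel = min(2 * p, match.shape[0])
        cum = np.concatenate(([0.0], np.cumsum(match)))
        frac = (cum[kernel:] - cum[:-kernel]) / kernel  # windowed match rate
        good = frac >= min_fraction_match
        if not good.any():
            continue
        edges = np.diff(good.astype(np.int8))
        starts = list(np.nonzero(edges == 1)[0] + 1)
        ends = list(np.nonzero(edges == -1)[0] + 1)
        if good[0]:
            starts.insert(0, 0)
        if good[-1]:
            ends.append(good.shape[0])
        # bridge dips shorter than one period inside an array
        runs = []
        for s, e in zip(starts, ends):
            if runs and s - runs[-1][1] <= p:
                runs[-1][1] = e
            else:
                runs.append([s, e])
        for s, e in runs:
            arr_start, arr_end = int(s), int(e) + kernel - 1 + p
            arr_end = min(arr_end, n)
            copy_n = (arr_end - arr_start) / p
            if copy_n < min_copies:
                continue
            m = float(cum[arr_end - p] - cum[arr_start])
            mlen = arr_end - arr_start - p
            if m - (mlen - m) < 24:  # +1/-1 significance over the array
                continue
            unit = codes[arr_start : arr_start + p]
            if np.unique(unit).shape[0] < 2:
                continue  # mono-base runs belong to simple repeats
            prior = covered.overlap(arr_start, arr_end)
            if any(
                min(arr_end, iv.end) - max(arr_start, iv.begin)
                >= 0.5 * (arr_end - arr_start)
                for iv in prior
            ):
                continue
            seg = codes[arr_start:arr_end]
            n_units = (arr_end - arr_start) // p
            stack = seg[: n_units * p].reshape(n_units, p)
            cons_unit = np.asarray(
                [np.bincount(stack[:, c], minlength=4).argmax() for c in range(p)],
                dtype=np.uint8,
            )
            pm = float(np.mean(codes[arr_start : arr_end - p] == codes[arr_start + p : arr_end]))
            covered[arr_start:arr_end] = p
            out.append(
                TandemArray(
                    interval=Interval(contig_id, arr_start, arr_end, "+", "tandem_repeat"),
                    period_bp=p,
                    copy_number=round(copy_n, 2),
                    consensus_unit=_seq.decode(cons_unit),
                    percent_matches=round(pm, 4),
                )
            )
    out.sort(key=lambda t: t.interval.start)
    return out


# ---------------------------------------------------------------------------
# simple / low-complexity repeats

_UNIT_MIN_COPIES = {1: 10, 2: 6, 3: 5, 4: 5}


def find_simple_repeats(
    contig: str,
    window: int = 64,
    entropy_bits: float = 1.0,
    unit_max: int = 4,
    contig_id: str = "contig",
) -> list[Interval]:
    """Low-entropy windows and short perfect unit runs, merged.

    A window qualifies when its base-composition entropy falls below
    ``entropy_bits``; a unit run qualifies when a 1-4 bp unit repeats
    perfectly at least 10/6/5/5 times respectively.
    """
    codes = _seq.encode(contig)
    n = codes.shape[0]
    mask = np.zeros(n, dtype=bool)
    labels: dict[int, str] = {}
    if n >= window:
        counts = np.zeros((4, n + 1), dtype=np.int64)
        for b in range(4):
            counts[b, 1:] = np.cumsum(codes == b)
        win_counts = counts[:, window:] - counts[:, :-window]
        tot = win_counts.sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = win_counts / np.maximum(tot, 1)
            ent = -np.nansum(np.where(p > 0, p * np.log2(p), 0.0), axis=0)
        low = np.nonzero((ent < entropy_bits) & (tot > window * 0.5))[0]
        for s in low:
            mask[s : s + window] = True
            labels.setdefault(int(s), "low_entropy")
    unit_names = {1: "mono", 2: "di", 3: "tri", 4: "tetra"}
    for u in range(1, unit_max + 1):
        need = (_UNIT_MIN_COPIES[u] - 1) * u  # length of the lag-match run
        if n <= u:
            continue
        m = codes[:-u] == codes[u:]
        edges = np.diff(m.astype(np.int8))
        starts = list(np.nonzero(edges == 1)[0] + 1)
        ends = list(np.nonzero(edges == -1)[0] + 1)
        if m[0]:
            starts.insert(0, 0)
        if m[-1]:
            ends.append(m.shape[0])
        for s, e in zip(starts, ends):
            if e - s >= need:
                # reject runs explained by a smaller unit
                if u > 1 and all(
                    np.all(codes[s + i] == codes[s]) for i in range(u)
                ):
                    continue
                mask[s : e + u] = True
                labels[int(s)] = unit_names[u]
    if not mask.any():
        return []
    edges = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(n)
    out = []
    for s, e in zip(starts, ends):
        label = labels.get(int(s), "simple_repeat")
        out.append(
            Interval(
                contig_id,
                int(s),
                int(e),
                ".",
                "simple_repeat",
                attributes={"class": label},
            )
        )
    return out


# ---------------------------------------------------------------------------
# nongenic ORF elements


def _orfs_in_frame(codes: np.ndarray, frame: int, min_len: int):
    """ATG..stop spans (longest ORF per stop) in one forward frame."""
    n = codes.shape[0]
    usable = (n - frame) // 3
    if usable < 2:
        return
    tri = codes[frame : frame + usable * 3].reshape(usable, 3)
    c27 = tri[:, 0].astype(np.int32) * 16 + tri[:, 1] * 4 + tri[:, 2]
    is_start = c27 == 0 * 16 + 3 * 4 + 2  # ATG
    stop_vals = {3 * 16 + 0 * 4 + 0, 3 * 16 + 0 * 4 + 2, 3 * 16 + 2 * 4 + 0}
    is_stop = np.isin(c27, list(stop_vals))
    prev_stop = -1
    starts = np.nonzero(is_start)[0]
    stops = np.nonzero(is_stop)[0]
    si = 0
    for stop in stops:
        while si < starts.shape[0] and starts[si] <= prev_stop:
            si += 1
        if si < starts.shape[0] and starts[si] < stop:
            length = (stop - starts[si] + 1) * 3
            if length >= min_len:
                yield frame + int(starts[si]) * 3, frame + (int(stop) + 1) * 3
        prev_stop = stop


def find_orf_elements(
    contig: str,
    gene_annotations: Optional[list[Interval]] = None,
    covmap: Optional[CoverageMap] = None,
    min_len: int = 240,
    contig_id: str = "contig",
) -> list[OrfElement]:
    """Long ORFs (both strands) outside annotated genes.

    ORFs overlapping an annotated gene/exon are dropped; overlapping
    survivors are reduced to the longest per cluster.  With a coverage
    map, each ORF is flagged when >= 50% of it lies in repetitive
    (depth >= 2) positions.
    """
    codes = _seq.encode(contig)
    n = codes.shape[0]
    raw: list[tuple[int, int, int]] = []  # start, end, frame (1..3, -1..-3)
    for frame in range(3):
        for s, e in _orfs_in_frame(codes, frame, min_len):
            raw.append((s, e, frame + 1))
    rc = _seq.revcomp(codes)
    for frame in range(3):
        for s, e in _orfs_in_frame(rc, frame, min_len):
            raw.append((n - e, n - s, -(frame + 1)))
    gene_tree = IntervalTree()
    if gene_annotations:
        for iv in gene_annotations:
            if iv.contig_id == contig_id and iv.label in ("gene", "exon", "mRNA", "CDS"):
                if iv.end <= iv.start:
                    raise ValueError("malformed annotation interval")
                gene_tree[iv.start : iv.end] = iv.label
    kept = [r for r in raw if not gene_tree.overlap(r[0], r[1])]
    kept.sort(key=lambda r: (r[0], -(r[1] - r[0])))
    # longest ORF per overlapping cluster
    clusters: list[list[tuple[int, int, int]]] = []
    for r in kept:
        if clusters and r[0] < max(x[1] for x in clusters[-1]):
            clusters[-1].append(r)
        else:
            clusters.append([r])
    out: list[OrfElement] = []
    for cl in clusters:
        s, e, frame = max(cl, key=lambda r: (r[1] - r[0], -r[0]))
        flag = None
        if covmap is not None:
            seg = covmap.depth[s:e]
            flag = bool(np.count_nonzero(seg >= 2) >= 0.5 * (e - s))
        strand = "+" if frame > 0 else "-"
        out.append(
            OrfElement(
                Interval(contig_id, s, e, strand, "orf_element"),
                frame=frame,
                overlaps_repetitive_coverage=flag,
            )
        )
    return out
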