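"""Local alignment of fixed-length reads against contigs.

The scoring scheme is the BLASTN-style +1/-1 with a linear gap cost of 2
per gap column (open = extend), so the dynamic program is a linear-gap
Smith-Waterman.  Two implementations coexist:

``find_hits``
    the production engine: exact-word seeding (word size 11 for strict
    identity, 8 for permissive) followed by full Smith-Waterman on merged
    candidate windows, jit-compiled with numba;
``sw_oracle``
    an independently written pure-numpy dynamic program over the whole
    contig, used as the verification oracle at test scale.

Both enumerate non-overlapping locally optimal alignments per strand by
greedy best-first extraction with segment splitting, then collapse
overlapping hits across strands to the best-scoring one.  Ties break by
smallest contig end, then smallest read end, then + strand.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from numba import njit

from . import _seq
from ._seq import KmerIndex


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 1
    mismatch: int = -1
    gap_open: int = 2
    gap_extend: int = 2
    word_size: int = 11

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open != self.gap_extend:
            raise ValueError("only linear gap costs (open == extend) are supported")
        if -self.gap_open > self.mismatch:
            raise ValueError("gap cost must be at least as severe as a mismatch")


DEFAULT_SCORING = ScoringScheme()


@dataclass
class AlignmentHit:
    read_id: str
    contig_id: str
    contig_start: int
    contig_end: int
    read_start: int
    read_end: int
    strand: str
    n_match: int
    n_mismatch: int
    n_gap_columns: int
    score: int

    @property
    def columns(self) -> int:
        return self.n_match + self.n_mismatch + self.n_gap_columns

    @property
    def identity(self) -> float:
        return self.n_match / self.columns


def identity_for_score(score: int, read_length: int) -> float:
    """Minimum identity of a full-length ungapped hit at a score cutoff.

    Under +1/-1 scoring a full-length read with m mismatches scores
    L - 2m, so the cutoff tolerates m = floor((L - score) / 2).
    """
    if score > read_length:
        raise ValueError("score cannot exceed read length")
    m = (read_length - score) // 2
    return (read_length - m) / read_length


# ---------------------------------------------------------------------------
# DP kernels.  Interface: (read_codes, contig_codes, match, mismatch, gap)
# -> (score, read_start, read_end, contig_start, contig_end,
#     n_match, n_mismatch, n_gap_columns); score 0 means no alignment.


@njit(cache=True)
def _sw_hit_numba(r, c, match, mismatch, gap):  # pragma: no cover - jitted
    m = r.shape[0]
    n = c.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for j in range(1, n + 1):
        cj = c[j - 1]
        for i in range(1, m + 1):
            ri = r[i - 1]
            s = match if (ri == cj and ri < 4) else mismatch
            v = H[i - 1, j - 1] + s
            v2 = H[i - 1, j] - gap
            if v2 > v:
                v = v2
            v3 = H[i, j - 1] - gap
            if v3 > v:
                v = v3
            if v < 0:
                v = 0
            H[i, j] = v
            if v > best:
                best = v
                bi = i
                bj = j
    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0, 0
    i = bi
    j = bj
    nm = 0
    nmm = 0
    ng = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        ri = r[i - 1]
        cj = c[j - 1]
        s = match if (ri == cj and ri < 4) else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            if s == match:
                nm += 1
            else:
                nmm += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] - gap:
            ng += 1
            i -= 1
        else:
            ng += 1
            j -= 1
    return best, i, bi, j, bj, nm, nmm, ng


def _sw_hit_numpy(r, c, match, mismatch, gap):
    """Reference DP: row-wise vectorized with a max-plus prefix scan."""
    m = len(r)
    n = len(c)
    if m == 0 or n == 0:
        return 0, 0, 0, 0, 0, 0, 0, 0
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    jj = np.arange(n, dtype=np.int64)
    c64 = c.astype(np.int64)
    for i in range(1, m + 1):
        ri = int(r[i - 1])
        s = np.where((c64 == ri) & (c64 < 4) & (ri < 4), match, mismatch)
        T = np.maximum(H[i - 1, :-1] + s, H[i - 1, 1:] - gap)
        np.maximum(T, 0, out=T)
        # close horizontal (contig-side) gap chains in one scan
        A = np.maximum.accumulate(T + gap * jj) - gap * jj
        H[i, 1:] = A
    best = int(H.max())
    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0, 0
    j, i = np.argwhere(H.T == best)[0]  # smallest contig end, then read end
    i = int(i)
    j = int(j)
    bi, bj = i, j
    nm = nmm = ng = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        s = match if (r[i - 1] == c[j - 1] and r[i - 1] < 4) else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            if s == match:
                nm += 1
            else:
                nmm += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] - gap:
            ng += 1
            i -= 1
        else:
            ng += 1
            j -= 1
    return best, i, bi, j, bj, nm, nmm, ng


# ---------------------------------------------------------------------------
# Greedy non-overlap enumeration (shared driver)


def _enumerate_segment(read_codes, contig_codes, lo, hi, cutoff, kernel):
    """Best-first extraction of non-overlapping hits within [lo, hi)."""
    out = []
    stack = [(lo, hi)]
    while stack:
        a, b = stack.pop()
        if b - a < 1:
            continue
        score, rs, re, cs, ce, nm, nmm, ng = kernel(read_codes, contig_codes[a:b])
        if score < cutoff:
            continue
        out.append((score, rs, re, a + cs, a + ce, nm, nmm, ng))
        stack.append((a, a + cs))
        stack.append((a + ce, b))
    return out


def _collapse(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Keep the best hit per contig locus when hits of one read overlap."""
    order = sorted(
        hits,
        key=lambda h: (-h.score, h.contig_end, h.read_end, h.strand == "-"),
    )
    kept: list[AlignmentHit] = []
    for h in order:
        clash = any(
            h.contig_start < k.contig_end and k.contig_start < h.contig_end
            for k in kept
        )
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: (h.contig_start, h.contig_end, h.strand))
    return kept


def _hits_for_strand(
    read_codes,
    read_len,
    contig_codes,
    segments,
    cutoff,
    kernel,
    strand,
    read_id,
    contig_id,
):
    raw = []
    for lo, hi in segments:
        raw.extend(_enumerate_segment(read_codes, contig_codes, lo, hi, cutoff, kernel))
    hits = []
    for score, rs, re, cs, ce, nm, nmm, ng in raw:
        if strand == "-":
            rs, re = read_len - re, read_len - rs
        hits.append(
            AlignmentHit(
                read_id=read_id,
                contig_id=contig_id,
                contig_start=cs,
                contig_end=ce,
                read_start=rs,
                read_end=re,
                strand=strand,
                n_match=nm,
                n_mismatch=nmm,
                n_gap_columns=ng,
                score=score,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# Production engine


class ContigIndex:
    """A contig plus lazily built k-mer position indexes."""

    def __init__(self, contig, contig_id: str = "contig"):
        if isinstance(contig, str):
            self.codes = _seq.encode(contig)
        elif hasattr(contig, "sequence"):
            self.codes = _seq.encode(contig.sequence)
            contig_id = contig.id
        else:
            self.codes = np.asarray(contig, dtype=np.uint8)
        self.id = contig_id
        self._indexes: dict[int, KmerIndex] = {}

    def __len__(self) -> int:
        return int(self.codes.shape[0])

    def index(self, k: int) -> KmerIndex:
        if k not in self._indexes:
            self._indexes[k] = KmerIndex(self.codes, k)
        return self._indexes[k]


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        return _seq.encode(seq)
    return np.asarray(seq, dtype=np.uint8)


def _candidate_windows(read_codes, index: KmerIndex, n: int, margin: int):
    vals, valid = _seq.kmer_ints(read_codes, index.k)
    vpos = np.nonzero(valid)[0]
    if vpos.size == 0:
        return []
    qi, cpos = index.lookup_many(vals[vpos])
    if cpos.size == 0:
        return []
    diags = cpos - vpos[qi]
    starts = np.maximum(diags - margin, 0)
    ends = np.minimum(diags + margin, n)
    order = np.argsort(starts, kind="stable")
    merged = []
    cur_s, cur_e = int(starts[order[0]]), int(ends[order[0]])
    for o in order[1:]:
        s, e = int(starts[o]), int(ends[o])
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            merged.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    merged.append((cur_s, cur_e))
    return merged


def _resolve_mode(read_len, scoring, min_score, min_identity, min_aln_len):
    if min_score is None and min_identity is None:
        min_identity = 0.75
    if min_score is not None:
        if min_score < 1:
            raise ValueError("score cutoff must be at least 1")
        cutoff = int(min_score)
        eff_identity = identity_for_score(min(min_score, read_len), read_len)
        aln_floor = 0 if min_aln_len is None else int(min_aln_len)
    else:
        if not (0.0 < min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")
        aln_floor = 30 if min_aln_len is None else int(min_aln_len)
        aln_floor = min(aln_floor, read_len)
        # significance floor mirroring the published permissive score
        # threshold of 24; weak gapped local alignments below it are
        # alignment noise, not repeat evidence
        cutoff = max(1, min(24, aln_floor))
        eff_identity = min_identity
    word = scoring.word_size if eff_identity >= 0.9 else 8
    return cutoff, min_identity, aln_floor, word


def find_hits(
    read,
    contig,
    scoring: ScoringScheme = DEFAULT_SCORING,
    min_score: Optional[int] = None,
    min_identity: Optional[float] = None,
    min_aln_len: Optional[int] = None,
    read_id: str = "read",
    contig_id: str = "contig",
) -> list[AlignmentHit]:
    """Seed-and-extend local alignment of one read against one contig.

    Exactly one stringency is applied: ``min_score`` (compatibility with
    the published score thresholds) or ``min_identity`` (the default,
    0.75).  In identity mode hits must also span ``min_aln_len`` columns
    (default 30).  Hits are returned sorted by contig start; overlapping
    hits of the read are collapsed to the best-scoring one per locus.
    """
    read_codes = _as_codes(read)
    if not isinstance(contig, ContigIndex):
        contig = ContigIndex(contig, contig_id)
    cutoff, ident_floor, aln_floor, word = _resolve_mode(
        read_codes.shape[0], scoring, min_score, min_identity, min_aln_len
    )
    if read_codes.shape[0] < word:
        raise ValueError("read shorter than the seeding word size")
    index = contig.index(word)
    n = len(contig)
    margin = read_codes.shape[0] + read_codes.shape[0] // 2 + 8
    hits: list[AlignmentHit] = []
    for strand, rc in (("+", read_codes), ("-", _seq.revcomp(read_codes))):
        windows = _candidate_windows(rc, index, n, margin)
        if not windows:
            continue
        hits.extend(
            _hits_for_strand(
                rc,
                read_codes.shape[0],
                contig.codes,
                windows,
                cutoff,
                _kernel_numba(scoring),
                strand,
                read_id,
                contig.id,
            )
        )
    if ident_floor is not None:
        hits = [h for h in hits if h.identity >= ident_floor]
    if aln_floor:
        hits = [h for h in hits if h.columns >= aln_floor]
    return _collapse(hits)


def _kernel_numba(scoring: ScoringScheme) -> Callable:
    match, mismatch, gap = scoring.match, scoring.mismatch, scoring.gap_open

    def kernel(r, c):
        return _sw_hit_numba(r, c, match, mismatch, gap)

    return kernel


def _kernel_numpy(scoring: ScoringScheme) -> Callable:
    match, mismatch, gap = scoring.match, scoring.mismatch, scoring.gap_open

    def kernel(r, c):
        return _sw_hit_numpy(r, c, match, mismatch, gap)

    return kernel


def sw_oracle(
    read,
    contig,
    scoring: ScoringScheme = DEFAULT_SCORING,
    cutoff: int = 1,
    read_id: str = "read",
    contig_id: str = "contig",
    max_contig: int = 10_000,
) -> list[AlignmentHit]:
    """Exhaustive Smith-Waterman over the whole contig (test scale only)."""
    read_codes = _as_codes(read)
    contig_codes = _as_codes(contig) if not isinstance(contig, ContigIndex) else contig.codes
    if isinstance(contig, ContigIndex):
        contig_id = contig.id
    if contig_codes.shape[0] > max_contig:
        raise ValueError(f"oracle restricted to contigs <= {max_contig} bp")
    if cutoff < 1:
        raise ValueError("score cutoff must be at least 1")
    kernel = _kernel_numpy(scoring)
    n = contig_codes.shape[0]
    hits: list[AlignmentHit] = []
    for strand, rc in (("+", read_codes), ("-", _seq.revcomp(read_codes))):
        hits.extend(
            _hits_for_strand(
                rc,
                read_codes.shape[0],
                contig_codes,
                [(0, n)],
                cutoff,
                kernel,
                strand,
                read_id,
                contig_id,
            )
        )
    return _collapse(hits)


def hits_for_pool(
    reads,
    contig,
    contig_id: str = "contig",
    **kwargs,
) -> list[AlignmentHit]:
    """``find_hits`` for every read of a pool against one shared contig index."""
    if not isinstance(contig, ContigIndex):
        contig = ContigIndex(contig, contig_id)
    all_hits: list[AlignmentHit] = []
    for i in range(reads.count):
        all_hits.extend(
            find_hits(reads.codes[i], contig, read_id=reads.read_id(i), **kwargs)
        )
    all_hits.sort(key=lambda h: (h.contig_start, h.contig_end, h.read_id))
    return all_hits


def hits_table(hits: list[AlignmentHit]):
    """BLAST outfmt-6-like table of hits."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "read_id": h.read_id,
                "contig_id": h.contig_id,
                "start": h.contig_start,
                "end": h.contig_end,
                "strand": h.strand,
                "score": h.score,
                "identity": round(h.identity, 4),
            }
            for h in hits
        ],
        columns=["read_id", "contig_id", "start", "end", "strand", "score", "identity"],
    )


def ungapped_matches(a: np.ndarray, b: np.ndarray) -> int:
    """Matching positions between equal-length code arrays (N never matches)."""
    return int(np.count_nonzero((a == b) & (a < 4)))
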