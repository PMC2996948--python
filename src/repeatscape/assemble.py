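"""Permissive consensus assembly of abundant repeats from sparse reads.

At well under 1x genome coverage no two reads are expected to sample the
same genomic locus, yet every abundant repeat family is sampled hundreds
of times across its dispersed copies.  The assembler exploits this: it
seeds on the most frequent k-mer in the pool, then grows a consensus by
recruiting reads that overlap the current end (either strand) at a
permissive identity and taking the most common base at each new column.
The product is a family consensus, not the sequence of any one genomic
copy.

Extension in a direction stops when the number of reads supporting a new
column falls below ``min_column_depth``; a circularity guard stops the
walk when the original seed k-mer reappears out of phase, which is the
signature of a tandem array.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _seq
from ._seq import shannon_entropy
from .seqio import ReadSet


class NoSeedError(RuntimeError):
    """No k-mer passes the frequency and complexity filters."""


@dataclass
class AssemblyParams:
    k: int = 16
    anchor_k: int = 8
    min_overlap_bp: int = 20
    min_overlap_identity: float = 0.80
    min_column_depth: int = 5
    max_elements: int = 3
    low_complexity_filter: bool = True
    seed_entropy_bits: float = 1.5
    chunk: int = 10
    max_length_bp: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 < self.min_overlap_identity <= 1.0):
            raise ValueError("min_overlap_identity must lie in (0.5, 1]")


@dataclass
class RepeatConsensus:
    name: str
    sequence: str
    supporting_read_count: int
    column_depth: np.ndarray
    structure: dict = field(default_factory=lambda: {"ltr_pair": None, "tandem_period": None})

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def element_length_bp(self) -> int:
        """Length reported for abundance: the unit for tandem elements."""
        if self.structure.get("tandem_period"):
            return int(self.structure["tandem_period"])
        return len(self.sequence)


class ReadKmerIndex:
    """k-mer -> (read, position, orientation) index over both strands."""

    def __init__(self, reads: ReadSet, k: int):
        self.k = k
        self.reads = reads
        N, L = reads.codes.shape
        if k > L:
            raise ValueError("k exceeds the read length")
        self.fwd = reads.codes
        self.rev = np.ascontiguousarray(
            np.where(reads.codes[:, ::-1] < 4, 3 - reads.codes[:, ::-1].astype(np.int8), 4)
        ).astype(np.uint8)
        vals_parts, ridx_parts, pos_parts, ori_parts = [], [], [], []
        for ori, mat in ((0, self.fwd), (1, self.rev)):
            flat = mat.ravel()
            vals, valid = _seq.kmer_ints(flat, k)
            # windows crossing read boundaries are not real k-mers
            w = L - k + 1
            grid = np.arange(N)[:, None] * L + np.arange(w)[None, :]
            v = vals[grid.ravel()]
            ok = valid[grid.ravel()]
            vals_parts.append(v[ok])
            rid = np.repeat(np.arange(N), w)[ok]
            ridx_parts.append(rid)
            pos_parts.append(np.tile(np.arange(w), N)[ok])
            ori_parts.append(np.full(ok.sum(), ori, dtype=np.int8))
        vals = np.concatenate(vals_parts)
        order = np.argsort(vals, kind="stable")
        self._vals = vals[order]
        self._ridx = np.concatenate(ridx_parts)[order]
        self._pos = np.concatenate(pos_parts)[order]
        self._ori = np.concatenate(ori_parts)[order]

    def oriented(self, ridx: int, ori: int) -> np.ndarray:
        return (self.rev if ori else self.fwd)[ridx]

    def lookup(self, val: int):
        lo = np.searchsorted(self._vals, val, side="left")
        hi = np.searchsorted(self._vals, val, side="right")
        return self._ridx[lo:hi], self._pos[lo:hi], self._ori[lo:hi]


def _canonical_kmer_counts(reads: ReadSet, k: int):
    N, L = reads.codes.shape
    flat = reads.codes.ravel()
    vals, valid = _seq.kmer_ints(flat, k)
    w = L - k + 1
    grid = (np.arange(N)[:, None] * L + np.arange(w)[None, :]).ravel()
    fwd = vals[grid][valid[grid]]
    rc_flat = np.where(flat[::-1] < 4, 3 - flat[::-1].astype(np.int8), 4).astype(np.uint8)
    rvals, rvalid = _seq.kmer_ints(rc_flat, k)
    # the reverse complement of the window starting at i starts at
    # n - k - i in the reversed-complemented flat sequence
    n = flat.shape[0]
    ridx = n - k - grid
    rev = rvals[ridx][valid[grid]]
    canon = np.minimum(fwd, rev)
    return np.unique(canon, return_counts=True)


def _decode_kmer(val: int, k: int) -> str:
    codes = np.empty(k, dtype=np.uint8)
    for t in range(k - 1, -1, -1):
        codes[t] = val & 3
        val >>= 2
    return _seq.decode(codes)


def select_seed(reads: ReadSet, params: AssemblyParams, min_count: int = 2) -> str:
    """Most frequent canonical k-mer passing the complexity filter.

    Ties break lexicographically (A < C < G < T).  Raises
    ``NoSeedError`` when nothing qualifies.
    """
    vals, counts = _canonical_kmer_counts(reads, params.k)
    order = np.lexsort((vals, -counts))
    for o in order:
        if counts[o] < min_count:
            break
        kmer = _decode_kmer(int(vals[o]), params.k)
        if params.low_complexity_filter:
            if shannon_entropy(_seq.encode(kmer)) < params.seed_entropy_bits:
                continue
        return kmer
    raise NoSeedError("no k-mer passes the frequency and complexity filters")


def _pool_base_order(reads: ReadSet) -> np.ndarray:
    """Base codes ordered by decreasing pool frequency (then A<C<G<T)."""
    counts = np.bincount(reads.codes.ravel(), minlength=5)[:4]
    return np.lexsort((np.arange(4), -counts))


def _candidates(index: ReadKmerIndex, window: np.ndarray, win_start: int):
    """(read, orientation, offset) of reads sharing a k-mer with ``window``.

    ``offset`` is the consensus coordinate at which the oriented read
    begins.
    """
    vals, valid = _seq.kmer_ints(window, index.k)
    seen = set()
    for q in np.nonzero(valid)[0]:
        ridx, pos, ori = index.lookup(int(vals[q]))
        for r, p, o in zip(ridx, pos, ori):
            seen.add((int(r), int(o), win_start + int(q) - int(p)))
    return sorted(seen)


def _wrap_check(cons: np.ndarray, n_old: int, kmer_first: dict, k: int = 16):
    """Detect the walk re-entering sequence it already produced.

    Registers every new consensus k-mer; a k-mer seen before at lag >= 5
    whose preceding context also matches is a wrap — the signature of a
    tandem unit (short lag) or of circling a terminal-repeat-bounded
    element (long lag).  Returns (trim_position, period) or None.
    """
    n_new = cons.shape[0]
    lo = max(0, n_old - k + 1)
    if n_new - lo < k:
        return None
    vals, _ = _seq.kmer_ints(cons[lo:], k)
    for i, val in enumerate(vals.tolist()):
        p = lo + i
        q = kmer_first.get(val)
        if q is not None and p - q >= 5:
            ctx = min(30, q)
            if ctx == 0 or (
                np.count_nonzero(cons[q - ctx : q] == cons[p - ctx : p]) / ctx >= 0.8
            ):
                return p, p - q
        if q is None:
            kmer_first[val] = p
    return None


def _extend_right(cons: np.ndarray, index: ReadKmerIndex, params: AssemblyParams,
                  base_order: np.ndarray, seed_codes: np.ndarray):
    """Grow ``cons`` rightwards until support drops; returns (cons, tandem_period)."""
    L = index.reads.read_length
    placed: dict = {}
    kmer_first: dict = {}
    _wrap_check(cons, 0, kmer_first)
    while cons.shape[0] < params.max_length_bp:
        n = cons.shape[0]
        # the seed itself is shorter than the overlap requirement, so the
        # requirement is capped by what is there to overlap
        ov_req = min(params.min_overlap_bp, n)
        win_start = max(0, n - (L + index.k))
        cands = _candidates(index, cons[win_start:], win_start)
        votes = np.zeros((params.chunk, 4), dtype=np.int64)
        for r, o, off in cands:
            rcodes = index.oriented(r, o)
            ov_lo, ov_hi = max(0, off), min(n, off + L)
            ov = ov_hi - ov_lo
            # anchors shorter than the overlap requirement are admitted
            # only down to 14 columns (and, below, only near-perfect):
            # a bare exact 8-mer would admit ~L/4^8 random voters per
            # column, enough to walk the consensus into noise
            if ov < min(14, ov_req) or off + L <= n:
                continue
            matches = np.count_nonzero(rcodes[ov_lo - off : ov_hi - off] == cons[ov_lo:ov_hi])
            # full-overlap reads anchor at the permissive identity; reads
            # with only a short anchor must match it near-perfectly
            if ov >= ov_req:
                if matches / ov < params.min_overlap_identity:
                    continue
            elif matches / ov < 0.95:
                continue
            placed[(r, o)] = off
            hi = min(off + L, n + params.chunk)
            for j in range(n, hi):
                b = rcodes[j - off]
                if b < 4:
                    votes[j - n, b] += 1
        new_cols = []
        for row in votes:
            # the frontier sees only reads anchored before the column, a
            # thinned and discovery-limited sample of the true column
            # depth, so extension runs on any evidence at all; the
            # configured depth floor is enforced on the final support
            # profile, which also prunes walk-offs past element ends
            depth = int(row.sum())
            if depth < 1:
                break
            best = max(row)
            tied = [b for b in range(4) if row[b] == best]
            if len(tied) > 1:
                tied.sort(key=lambda b: list(base_order).index(b))
            new_cols.append(tied[0])
        if not new_cols:
            return cons, None
        n_old = cons.shape[0]
        cons = np.concatenate([cons, np.asarray(new_cols, dtype=np.uint8)])
        wrap = _wrap_check(cons, n_old, kmer_first)
        if wrap is not None:
            trim, period = wrap
            return cons[:trim], period
    return cons, None


def _find_occurrences(hay: np.ndarray, needle: np.ndarray) -> np.ndarray:
    k = needle.shape[0]
    if hay.shape[0] < k:
        return np.empty(0, np.int64)
    w = hay.shape[0] - k + 1
    ok = np.ones(w, dtype=bool)
    for t in range(k):
        ok &= hay[t : t + w] == needle[t]
    return np.nonzero(ok)[0]


def _support(cons: np.ndarray, index: ReadKmerIndex, params: AssemblyParams):
    """Final recruitment: per-column depth and the supporting read mask."""
    L = index.reads.read_length
    n = cons.shape[0]
    depth = np.zeros(n, dtype=np.int64)
    mask = np.zeros(index.reads.count, dtype=bool)
    step = L + index.k
    seen = set()
    for win_start in range(0, max(1, n - index.k + 1), max(1, step - index.k)):
        window = cons[win_start : win_start + step]
        for r, o, off in _candidates(index, window, win_start):
            if (r, o, off) in seen:
                continue
            seen.add((r, o, off))
            rcodes = index.oriented(r, o)
            ov_lo, ov_hi = max(0, off), min(n, off + L)
            if ov_hi - ov_lo < params.min_overlap_bp:
                continue
            ov = ov_hi - ov_lo
            matches = np.count_nonzero(rcodes[ov_lo - off : ov_hi - off] == cons[ov_lo:ov_hi])
            if matches / ov < params.min_overlap_identity:
                continue
            depth[ov_lo:ov_hi] += 1
            mask[r] = True
    return depth, mask


def extend_consensus(
    reads: ReadSet,
    seed: str,
    params: AssemblyParams,
    index: Optional[ReadKmerIndex] = None,
    name: str = "element",
) -> RepeatConsensus:
    """Greedy bidirectional majority-rule extension from a seed k-mer."""
    if index is None:
        index = ReadKmerIndex(reads, params.anchor_k)
    seed_codes = _seq.encode(seed)
    if not _seed_present(index, seed_codes):
        raise ValueError("seed k-mer absent from the read pool")
    base_order = _pool_base_order(reads)
    cons, period = _extend_right(seed_codes.copy(), index, params, base_order, seed_codes)
    if period is None:
        # the left direction is a right extension of the reverse complement
        rc, period_rc = _extend_right(
            _seq.revcomp(cons), index, params, base_order, _seq.revcomp(seed_codes)
        )
        cons = _seq.revcomp(rc)
        period = period_rc
    tandem_p = wrap_p = None
    if period is not None:
        p = _minimal_period(cons, period)
        if p <= 200:
            # tandem unit: represent it tiled past one unit plus a read
            # length so reads spanning unit junctions can be recruited
            tandem_p = p
            L = reads.read_length
            unit = cons[:p]
            reps = math.ceil((2 * p + L) / p)
            cons = np.tile(unit, reps)[: 2 * p + L]
        else:
            wrap_p = p
    depth, mask = _support(cons, index, params)
    # trim terminal columns that lost support in the final recruitment
    keep = np.nonzero(depth >= min(params.min_column_depth, int(depth.max()) if depth.size else 0))[0]
    if keep.size:
        cons = cons[keep[0] : keep[-1] + 1]
        depth = depth[keep[0] : keep[-1] + 1]
    rc = RepeatConsensus(
        name=name,
        sequence=_seq.decode(cons),
        supporting_read_count=int(mask.sum()),
        column_depth=depth,
    )
    if tandem_p is not None:
        rc.structure["tandem_period"] = tandem_p
    if wrap_p is not None:
        # a long wrap means the walk circled a dispersed element
        # (interior -> terminal repeat -> interior); the consensus is
        # the interior plus one terminal repeat copy
        rc.structure["wrap_period"] = wrap_p
    return rc


def _seed_present(index: ReadKmerIndex, seed_codes: np.ndarray) -> bool:
    vals, _ = _seq.kmer_ints(seed_codes, index.k)
    ridx, pos, ori = index.lookup(int(vals[0]))
    L = index.reads.read_length
    for r, p, o in zip(ridx, pos, ori):
        rcodes = index.oriented(int(r), int(o))
        end = int(p) + seed_codes.shape[0]
        if end <= L and np.array_equal(rcodes[int(p):end], seed_codes):
            return True
    return False


def _minimal_period(cons: np.ndarray, period: int) -> int:
    """Smallest divisor of the detected lag that still explains the repeat."""
    for p in range(1, period):
        if period % p:
            continue
        n = cons.shape[0] - p
        if n >= p and np.count_nonzero(cons[:-p] == cons[p:]) / n >= 0.9:
            return p
    return period


def detect_structure(
    consensus: str,
    min_ltr_bp: int = 50,
    ltr_identity: float = 0.80,
    period_range: tuple[int, int] = (5, 200),
    tandem_fraction: float = 0.8,
) -> dict:
    """Self-alignment annotations of a consensus.

    Reports (a) the best terminal direct-repeat pair of >= ``min_ltr_bp``
    at >= ``ltr_identity`` as a candidate LTR pair, and (b) the smallest
    autocorrelation period in ``period_range`` whose lag-matches hold
    over >= 80% of the sequence as a tandem period.
    """
    codes = _seq.encode(consensus)
    L = codes.shape[0]
    if L < 50:
        raise ValueError("consensus too short for structure detection")
    out: dict = {"ltr_pair": None, "tandem_period": None}
    for p in range(period_range[0], min(period_range[1], L // 2) + 1):
        n = L - p
        if n < max(p, int(math.ceil(tandem_fraction * L)) - p):
            continue
        frac = np.count_nonzero(codes[:-p] == codes[p:]) / n
        if frac >= tandem_fraction and len(set(consensus[:p])) >= 2:
            out["tandem_period"] = p
            return out
    best = None
    for l in range(min_ltr_bp, L // 2 + 1):
        lag = L - l
        matches = int(np.count_nonzero(codes[:l] == codes[lag:]))
        ident = matches / l
        if ident < ltr_identity:
            continue
        score = l * (2 * ident - 1)
        if best is None or score > best[0]:
            best = (score, l, lag, ident)
    if best is not None:
        _, l, lag, ident = best
        out["ltr_pair"] = (0, l, lag, lag + l, round(ident, 4))
    return out


def assemble_top_repeats(
    reads: ReadSet,
    params: AssemblyParams,
) -> list[RepeatConsensus]:
    """Iterate seed -> extend -> subtract; rank by supporting reads.

    Each round removes every read matching the new consensus at the
    overlap identity, so the pool size strictly decreases; the loop ends
    after ``max_elements`` elements or when no k-mer remains frequent
    enough to seed (the situation for a pure-background pool).
    """
    pool = reads
    out: list[RepeatConsensus] = []
    n_el = 0
    while n_el < params.max_elements and pool.count > 0:
        try:
            seed = select_seed(pool, params, min_count=max(2, params.min_column_depth))
        except NoSeedError:
            break
        index = ReadKmerIndex(pool, params.anchor_k)
        cons = extend_consensus(pool, seed, params, index=index, name=f"element_{n_el + 1}")
        struct = detect_structure(cons.sequence) if len(cons) >= 50 else {
            "ltr_pair": None,
            "tandem_period": None,
        }
        if cons.structure.get("tandem_period") and not struct.get("tandem_period"):
            struct["tandem_period"] = cons.structure["tandem_period"]
        if cons.structure.get("wrap_period"):
            struct["wrap_period"] = cons.structure["wrap_period"]
        cons.structure = struct
        _, mask = _support(_seq.encode(cons.sequence), index, params)
        out.append(cons)
        n_el += 1
        if not mask.any():
            break
        pool = pool.subset(~mask)
    out.sort(key=lambda c: -c.supporting_read_count)
    return out


def tiled_reference(cons: RepeatConsensus, read_length: int) -> str:
    """Reference sequence for abundance counting.

    Tandem units are tiled to at least one unit plus a read length so
    reads spanning unit junctions can still cover 90% of their length;
    non-tandem consensi are used as-is.
    """
    p = cons.structure.get("tandem_period")
    if not p:
        return cons.sequence
    unit = cons.sequence[:p]
    reps = math.ceil((read_length + p) / p) + 1
    return (unit * reps)[: p * reps]
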