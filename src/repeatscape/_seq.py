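"""Low-level nucleotide encoding and k-mer machinery.

Sequences are held internally as ``uint8`` code arrays with A=0, C=1, G=2,
T=3, N=4.  The numeric order matches lexicographic base order, so integer
comparisons of packed k-mers coincide with lexicographic tie-breaks.
"""
from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
# RNA input is accepted and mapped onto the DNA alphabet.
_CODE[ord("U")] = 3
_CODE[ord("u")] = 3

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 code array.

    Raises ``ValueError`` naming the first illegal character.
    """
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _CODE[raw]
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        raise ValueError(
            f"illegal character {seq[bad[0]]!r} at position {int(bad[0])}"
        )
    return codes


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array; N (code 4) maps to itself."""
    rc = codes[::-1]
    return np.where(rc < 4, 3 - rc.astype(np.int8), rc).astype(np.uint8)


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def kmer_ints(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack every k-window into a base-4 integer.

    Returns ``(vals, valid)`` over start positions ``0 .. n-k``; windows
    containing N are flagged invalid (their packed value is meaningless).
    Requires ``k <= 31`` so the value fits an int64.
    """
    n = codes.shape[0]
    if k > 31:
        raise ValueError("k-mer size above 31 not supported")
    if n < k:
        return np.empty(0, np.int64), np.empty(0, bool)
    m = n - k + 1
    vals = np.zeros(m, dtype=np.int64)
    safe = np.where(codes < 4, codes, 0).astype(np.int64)
    for t in range(k):
        vals += safe[t : t + m] << (2 * (k - 1 - t))
    bad = (codes >= 4).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (cum[k:] - cum[:-k]) == 0
    return vals, valid


class KmerIndex:
    """Sorted-array index from packed k-mer value to start positions."""

    def __init__(self, codes: np.ndarray, k: int):
        self.k = k
        self.n = codes.shape[0]
        vals, valid = kmer_ints(codes, k)
        pos = np.nonzero(valid)[0]
        vals = vals[pos]
        order = np.argsort(vals, kind="stable")
        self._vals = vals[order]
        self._pos = pos[order].astype(np.int64)

    def lookup(self, val: int) -> np.ndarray:
        lo = np.searchsorted(self._vals, val, side="left")
        hi = np.searchsorted(self._vals, val, side="right")
        return self._pos[lo:hi]

    def lookup_many(self, vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Positions for a vector of query values.

        Returns ``(query_idx, positions)`` parallel arrays.
        """
        lo = np.searchsorted(self._vals, vals, side="left")
        hi = np.searchsorted(self._vals, vals, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        qi = np.repeat(np.arange(vals.shape[0]), counts)
        offs = np.concatenate(
            [np.arange(l, h) for l, h, c in zip(lo, hi, counts) if c]
        )
        return qi, self._pos[offs]


def shannon_entropy(codes: np.ndarray) -> float:
    """Base-composition Shannon entropy (bits) over non-N positions."""
    counts = np.bincount(codes[codes < 4], minlength=4).astype(float)
    tot = counts.sum()
    if tot == 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())
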