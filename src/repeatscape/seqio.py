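"""Standard-format I/O: FASTA, FASTQ, GFF3, .sgr, BED.

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
inclusive) and .sgr (1-based) are converted at the boundary.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import _seq


class SeqIOError(ValueError):
    """Base class for format-contract violations."""


class DuplicateIdError(SeqIOError):
    pass


class EmptyRecordError(SeqIOError):
    pass


class IllegalCharacterError(SeqIOError):
    pass


class MixedLengthError(SeqIOError):
    pass


class FormatError(SeqIOError):
    pass


@dataclass
class SeqRecord:
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("record id must be non-empty")
        if not self.sequence:
            raise EmptyRecordError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        return _seq.encode(self.sequence)


@dataclass
class Interval:
    """Half-open genomic interval with GFF3-compatible payload."""

    contig_id: str
    start: int
    end: int
    strand: str = "."
    label: str = "region"
    attributes: dict = field(default_factory=dict)
    source: str = "repeatscape"
    score: str = "."
    phase: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise SeqIOError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig_id}"
            )
        if self.strand not in "+-.":
            raise SeqIOError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class ReadSet:
    """A pool of fixed-length unassembled reads.

    Reads are stored as an ``(N, L)`` uint8 code matrix.  ``coverage`` is
    genome equivalents (total bases / genome size) when the genome the
    pool was drawn from is known.
    """

    codes: np.ndarray
    ids: Optional[list[str]] = None
    coverage: Optional[float] = None
    source_start: Optional[np.ndarray] = None
    source_strand: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.codes.ndim != 2:
            raise ValueError("read codes must be a 2-D (N, L) array")

    @property
    def count(self) -> int:
        return int(self.codes.shape[0])

    @property
    def read_length(self) -> int:
        return int(self.codes.shape[1])

    @property
    def total_bases(self) -> int:
        return self.count * self.read_length

    def sequence(self, i: int) -> str:
        return _seq.decode(self.codes[i])

    def sequences(self) -> Iterable[str]:
        for i in range(self.count):
            yield self.sequence(i)

    def read_id(self, i: int) -> str:
        return self.ids[i] if self.ids is not None else f"read_{i}"

    def subset(self, keep: np.ndarray) -> "ReadSet":
        ids = [self.ids[i] for i in np.nonzero(keep)[0]] if self.ids else None
        return ReadSet(
            self.codes[keep],
            ids=ids,
            coverage=None,
            source_start=None if self.source_start is None else self.source_start[keep],
            source_strand=None if self.source_strand is None else self.source_strand[keep],
        )

    @classmethod
    def from_strings(cls, seqs: Sequence[str], ids: Optional[list[str]] = None) -> "ReadSet":
        if not seqs:
            raise EmptyRecordError("read pool is empty")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            off = next(
                (ids[i] if ids else f"read index {i}")
                for i, s in enumerate(seqs)
                if len(s) != len(seqs[0])
            )
            raise MixedLengthError(
                f"reads have mixed lengths {sorted(lengths)}; first offender: {off}"
            )
        codes = np.stack([_seq.encode(s) for s in seqs])
        return cls(codes, ids=list(ids) if ids is not None else None)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _normalise(seq: str, rec_id: str) -> str:
    try:
        return _seq.decode(_seq.encode(seq))
    except ValueError as exc:
        raise IllegalCharacterError(f"record {rec_id!r}: {exc}") from None


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Read FASTA; uppercases, maps U->T, rejects non-ACGTNU characters."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            parts = title.split(None, 1)
            if not parts:
                raise FormatError(f"{path}: FASTA header with no id")
            rec_id = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            if rec_id in seen:
                raise DuplicateIdError(f"{path}: duplicate record id {rec_id!r}")
            seen.add(rec_id)
            if not seq:
                raise EmptyRecordError(f"{path}: record {rec_id!r} is empty")
            records.append(SeqRecord(rec_id, _normalise(seq, rec_id), desc))
    if not records:
        raise EmptyRecordError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Sequence[SeqRecord], path: str | os.PathLike, wrap: int = 60):
    if not records:
        raise EmptyRecordError("refusing to write an empty FASTA")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i : i + wrap] + "\n")
    return path


def read_reads(path: str | os.PathLike, format: str = "fasta") -> ReadSet:
    """Read a fixed-length pool; FASTQ qualities are parsed then discarded."""
    if format == "fasta":
        recs = read_fasta(path)
        ids = [r.id for r in recs]
        seqs = [r.sequence for r in recs]
    elif format == "fastq":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        ids, seqs = [], []
        with open(path) as fh:
            try:
                for title, seq, _qual in FastqGeneralIterator(fh):
                    ids.append(title.split(None, 1)[0])
                    seqs.append(_normalise(seq, ids[-1]))
            except ValueError as exc:
                raise FormatError(f"{path}: bad FASTQ structure: {exc}") from None
        if not seqs:
            raise EmptyRecordError(f"{path}: no FASTQ records")
    else:
        raise ValueError(f"unknown read format {format!r}")
    return ReadSet.from_strings(seqs, ids=ids)


def write_reads_fasta(reads: ReadSet, path: str | os.PathLike, wrap: int = 60):
    recs = [SeqRecord(reads.read_id(i), reads.sequence(i)) for i in range(reads.count)]
    return write_fasta(recs, path, wrap=wrap)


# ---------------------------------------------------------------------------
# .sgr coverage serialization (1-based, dense)


def write_sgr(covmap, path: str | os.PathLike):
    """Write a coverage map as contig <TAB> 1-based position <TAB> depth."""
    depth = np.asarray(covmap.depth)
    if depth.size == 0:
        raise SeqIOError("refusing to write an empty coverage map")
    with open(path, "w") as fh:
        for i, d in enumerate(depth, start=1):
            fh.write(f"{covmap.contig_id}\t{i}\t{int(d)}\n")
    return path


def read_sgr(path: str | os.PathLike) -> tuple[str, np.ndarray]:
    """Read back one contig's .sgr; checks 1-based dense ascending positions."""
    contig = None
    depths: list[int] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 3:
                raise FormatError(f"{path}:{ln}: expected 3 columns")
            cid, pos, val = cols
            if contig is None:
                contig = cid
            elif cid != contig:
                raise FormatError(f"{path}:{ln}: multiple contigs in one .sgr")
            if int(pos) != ln:
                raise FormatError(f"{path}:{ln}: positions not dense/1-based")
            depths.append(int(val))
    if contig is None:
        raise EmptyRecordError(f"{path}: empty .sgr")
    return contig, np.asarray(depths, dtype=np.int64)


# ---------------------------------------------------------------------------
# GFF3 (v1.2 dialect, attributes as key=value;... in column 9)


def _fmt_attrs(attrs: dict) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def _parse_attrs(field9: str) -> dict:
    if field9 in (".", ""):
        return {}
    out = {}
    for item in field9.rstrip(";").split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
        else:
            out[item] = ""
    return out


def read_gff3(path: str | os.PathLike) -> list[Interval]:
    intervals: list[Interval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{ln}: expected 9 columns, got {len(cols)}")
            seqid, source, ftype, start, end, score, strand, phase, attrs = cols
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise FormatError(f"{path}:{ln}: end < start")
            intervals.append(
                Interval(
                    contig_id=seqid,
                    start=start_i - 1,
                    end=end_i,
                    strand=strand if strand in "+-." else ".",
                    label=ftype,
                    attributes=_parse_attrs(attrs),
                    source=source,
                    score=score,
                    phase=phase,
                )
            )
    return intervals


def write_gff3(intervals: Iterable[Interval], path: str | os.PathLike):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in intervals:
            fh.write(
                "\t".join(
                    [
                        iv.contig_id,
                        iv.source,
                        iv.label,
                        str(iv.start + 1),
                        str(iv.end),
                        iv.score,
                        iv.strand,
                        iv.phase,
                        _fmt_attrs(iv.attributes),
                    ]
                )
                + "\n"
            )
    return path


def write_bed(intervals: Iterable[Interval], path: str | os.PathLike):
    """BED6 export (0-based half-open, as BED requires)."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.attributes.get("Name", iv.label)
            score = iv.score if iv.score != "." else "0"
            strand = iv.strand if iv.strand != "." else "."
            fh.write(
                f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{strand}\n"
            )
    return path
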