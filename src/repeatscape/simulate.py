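"""Synthetic genomes with planted repeat structure, plus WGS read pools.

The generator emulates the architecture inferred for very large conifer
genomes: a handful of young, near-identical LTR retroelement families on
top of a dominant background of ancient, heavily diverged and fragmented
elements, tandem (minisatellite) arrays including a 50-bp centromere-like
unit, telomeric TTTAGGG arrays, low-complexity tracts, and compact
genes with an excess of pseudogene copies.  Every placed feature is
recorded in a ground-truth ledger so estimators can be scored exactly.

Divergence is substitution-only by default: each copy of a family is the
family consensus mutated independently at the per-base ``divergence``
rate, so the ledger's ``identity`` attribute is exact.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _seq
from .seqio import Interval, ReadSet, SeqRecord, write_fasta, write_gff3

TELOMERE_UNIT = "TTTAGGG"


@dataclass
class RepeatFamilySpec:
    """One planted repeat family.

    For ``ltr_retro`` kinds, ``consensus_length_bp`` is the full element
    length including both terminal repeats and ``copy_count`` is the
    number of dispersed copies.  For ``tandem``/``telomeric``/
    ``low_complexity`` kinds, ``consensus_length_bp`` is the unit length,
    ``copy_count`` the total number of tandem units, and units are placed
    as arrays of up to ``array_size`` units.
    """

    name: str
    consensus_length_bp: int
    copy_count: int
    divergence: float = 0.0
    ltr_length_bp: int = 0
    fragmentation_prob: float = 0.0
    nesting_prob: float = 0.0
    kind: str = "ltr_retro"
    unit: Optional[str] = None
    array_size: int = 100

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 0.5):
            raise ValueError("divergence must lie in [0, 0.5]")
        if self.ltr_length_bp < 0 or 2 * self.ltr_length_bp >= self.consensus_length_bp:
            raise ValueError("terminal repeats must fit inside the element")
        if self.copy_count < 1:
            raise ValueError("copy_count must be >= 1")
        if self.kind not in ("ltr_retro", "tandem", "telomeric", "low_complexity"):
            raise ValueError(f"unknown family kind {self.kind!r}")
        if self.kind == "telomeric" and self.unit is None:
            self.unit = TELOMERE_UNIT
        if self.unit is not None:
            self.consensus_length_bp = len(self.unit)

    @property
    def is_tandem(self) -> bool:
        return self.kind in ("tandem", "telomeric", "low_complexity")


@dataclass
class GenomeSpec:
    genome_length_bp: int
    base_composition: tuple[float, float, float, float] = (0.30, 0.20, 0.20, 0.30)
    families: list[RepeatFamilySpec] = field(default_factory=list)
    gene_count: int = 0
    pseudogene_ratio: int = 5
    seed: int = 0
    contig_id: str = "g1"

    def __post_init__(self) -> None:
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")


@dataclass
class ReadSimSpec:
    read_length_bp: int = 60
    coverage: float = 0.036
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not (0.0 <= self.error_rate <= 0.1):
            raise ValueError("error_rate must lie in [0, 0.1]")


@dataclass
class GenomeTruth:
    records: list[SeqRecord]
    placements: list[Interval]
    consensi: dict[str, str]
    spec: GenomeSpec

    @property
    def genome_length(self) -> int:
        return sum(len(r) for r in self.records)

    @property
    def codes(self) -> np.ndarray:
        return _seq.encode(self.records[0].sequence)

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        write_fasta(self.records, os.path.join(outdir, "genome.fasta"))
        write_gff3(self.placements, os.path.join(outdir, "truth.gff3"))
        if self.consensi:
            write_fasta(
                [SeqRecord(name, seq) for name, seq in self.consensi.items()],
                os.path.join(outdir, "consensi.fasta"),
            )


# ---------------------------------------------------------------------------
# mutation helpers


def _random_codes(rng, n, comp) -> np.ndarray:
    return rng.choice(4, size=n, p=np.asarray(comp)).astype(np.uint8)


def _mutate(rng, codes: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return codes.copy()
    out = codes.copy()
    hit = np.nonzero(rng.random(codes.shape[0]) < rate)[0]
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size).astype(np.uint8)
        out[hit] = (out[hit] + shift) % 4
    return out


class _Unit:
    """A contiguous block to be spliced into the background, with its
    ledger entries in unit-relative coordinates."""

    __slots__ = ("codes", "entries", "nestable")

    def __init__(self, codes, entries, nestable=False):
        self.codes = codes
        self.entries = entries  # list of [rel_start, rel_end, label, strand, attrs]
        self.nestable = nestable

    def insert(self, off: int, other: "_Unit", host_copy: str) -> None:
        ilen = other.codes.shape[0]
        new_entries = []
        for s, e, label, strand, attrs in self.entries:
            if e <= off:
                new_entries.append([s, e, label, strand, attrs])
            elif s >= off:
                new_entries.append([s + ilen, e + ilen, label, strand, attrs])
            else:  # split the containing entry into flanking fragments
                left = [s, off, label, strand, dict(attrs, fragment="1")]
                right = [off + ilen, e + ilen, label, strand, dict(attrs, fragment="2")]
                new_entries.extend([left, right])
        for s, e, label, strand, attrs in other.entries:
            new_entries.append(
                [s + off, e + off, label, strand, dict(attrs, nested_in=host_copy)]
            )
        self.entries = sorted(new_entries, key=lambda x: x[0])
        self.codes = np.concatenate([self.codes[:off], other.codes, self.codes[off:]])
        self.nestable = False

    def flip(self) -> None:
        L = self.codes.shape[0]
        self.codes = _seq.revcomp(self.codes)
        flipped = []
        for s, e, label, strand, attrs in self.entries:
            strand = {"+": "-", "-": "+", ".": "."}[strand]
            flipped.append([L - e, L - s, label, strand, attrs])
        self.entries = sorted(flipped, key=lambda x: x[0])


def _build_family_units(rng, fam: RepeatFamilySpec, comp, consensi) -> list[_Unit]:
    units: list[_Unit] = []
    if fam.is_tandem:
        if fam.unit is not None:
            unit_codes = _seq.encode(fam.unit)
        else:
            unit_codes = _random_codes(rng, fam.consensus_length_bp, comp)
        consensi[fam.name] = _seq.decode(unit_codes)
        n_arrays = math.ceil(fam.copy_count / fam.array_size)
        left = fam.copy_count
        for ai in range(n_arrays):
            n_units = min(fam.array_size, left)
            left -= n_units
            copies = [_mutate(rng, unit_codes, fam.divergence) for _ in range(n_units)]
            codes = np.concatenate(copies)
            matches = sum(
                int(np.count_nonzero(c == unit_codes)) for c in copies
            )
            ident = matches / codes.shape[0]
            attrs = {
                "family": fam.name,
                "copy": f"{fam.name}.a{ai}",
                "identity": f"{ident:.4f}",
                "n_units": str(n_units),
                "kind": fam.kind,
            }
            units.append(_Unit(codes, [[0, codes.shape[0], fam.name, "+", attrs]]))
        return units

    # dispersed (LTR retroelement-like) family: consensus carries
    # identical-at-birth terminal repeats which then diverge per copy
    L, ltr = fam.consensus_length_bp, fam.ltr_length_bp
    if ltr > 0:
        ltr_codes = _random_codes(rng, ltr, comp)
        mid = _random_codes(rng, L - 2 * ltr, comp)
        consensus = np.concatenate([ltr_codes, mid, ltr_codes])
    else:
        consensus = _random_codes(rng, L, comp)
    consensi[fam.name] = _seq.decode(consensus)
    for ci in range(fam.copy_count):
        copy = _mutate(rng, consensus, fam.divergence)
        ref = consensus
        truncated = False
        if fam.fragmentation_prob > 0 and rng.random() < fam.fragmentation_prob:
            keep = max(50, int(round(rng.uniform(0.3, 0.8) * L)))
            off = int(rng.integers(0, L - keep + 1))
            copy = copy[off : off + keep]
            ref = consensus[off : off + keep]
            truncated = True
        ident = np.count_nonzero(copy == ref) / copy.shape[0]
        attrs = {
            "family": fam.name,
            "copy": f"{fam.name}.c{ci}",
            "identity": f"{ident:.4f}",
            "truncated": "1" if truncated else "0",
            "kind": fam.kind,
        }
        nestable = not truncated and copy.shape[0] >= 400
        units.append(
            _Unit(copy, [[0, copy.shape[0], fam.name, "+", attrs]], nestable=nestable)
        )
    return units


def _build_gene_units(rng, spec: GenomeSpec, comp) -> list[_Unit]:
    """Compact multi-exon genes plus diverged pseudogene copies.

    Structure follows the compact-gene picture: ~3 exons of ~220 bp with
    introns of a few hundred bp.  Pseudogenes are gene copies mutated at
    10% and usually truncated.
    """
    units: list[_Unit] = []
    templates = []
    for gi in range(spec.gene_count):
        n_exons = int(rng.integers(2, 5))
        parts = []
        entries = []
        pos = 0
        for ei in range(n_exons):
            elen = int(rng.integers(150, 290))
            exon = _random_codes(rng, elen, comp)
            parts.append(exon)
            entries.append(
                [pos, pos + elen, "exon", "+", {"gene": f"gene{gi}", "exon": str(ei)}]
            )
            pos += elen
            if ei < n_exons - 1:
                ilen = int(rng.integers(200, 500))
                parts.append(_random_codes(rng, ilen, comp))
                pos += ilen
        codes = np.concatenate(parts)
        gene_entry = [0, codes.shape[0], "gene", "+", {"gene": f"gene{gi}", "copy": f"gene{gi}"}]
        units.append(_Unit(codes, [gene_entry] + entries))
        templates.append(codes)
    n_pseudo = spec.gene_count * spec.pseudogene_ratio
    for pi in range(n_pseudo):
        tmpl = templates[int(rng.integers(0, len(templates)))]
        copy = _mutate(rng, tmpl, 0.10)
        if rng.random() < 0.5:
            keep = max(100, int(round(rng.uniform(0.4, 0.9) * copy.shape[0])))
            off = int(rng.integers(0, copy.shape[0] - keep + 1))
            copy = copy[off : off + keep]
        attrs = {"copy": f"pseudo{pi}"}
        units.append(_Unit(copy, [[0, copy.shape[0], "pseudogene", "+", attrs]]))
    return units


def simulate_genome(spec: GenomeSpec) -> GenomeTruth:
    """Build the genome and its complete placement ledger.

    Background bases are i.i.d. from ``base_composition``; planted units
    are spliced in at uniform positions (insertion model, so units never
    overlap except through explicit nesting).  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    comp = np.asarray(spec.base_composition)
    consensi: dict[str, str] = {}
    units: list[_Unit] = []
    nest_flags: list[bool] = []
    for fam in spec.families:
        fam_units = _build_family_units(rng, fam, comp, consensi)
        units.extend(fam_units)
        nest_flags.extend(
            (not fam.is_tandem) and rng.random() < fam.nesting_prob for _ in fam_units
        )
    gene_units = _build_gene_units(rng, spec, comp) if spec.gene_count else []
    units.extend(gene_units)
    nest_flags.extend(False for _ in gene_units)

    # nesting: a flagged copy is inserted inside an eligible host copy,
    # splitting the host into two ledger fragments
    placed: list[_Unit] = []
    for unit, nest in zip(units, nest_flags):
        if nest:
            hosts = [u for u in placed if u.nestable]
            if hosts:
                host = hosts[int(rng.integers(0, len(hosts)))]
                hlen = host.codes.shape[0]
                off = int(rng.integers(100, hlen - 100 + 1))
                host.insert(off, unit, host.entries[0][4].get("copy", "host"))
                continue
        placed.append(unit)
    units = placed

    for unit in units:
        if rng.random() < 0.5:
            unit.flip()

    total_unit_bp = sum(u.codes.shape[0] for u in units)
    background_bp = spec.genome_length_bp - total_unit_bp
    if background_bp < 0:
        raise ValueError(
            f"planted features ({total_unit_bp} bp) exceed genome length "
            f"({spec.genome_length_bp} bp)"
        )
    order = rng.permutation(len(units))
    units = [units[i] for i in order]
    offsets = np.sort(rng.integers(0, background_bp + 1, size=len(units)))
    background = _random_codes(rng, background_bp, comp)

    pieces = []
    placements: list[Interval] = []
    prev = 0
    genome_pos = 0
    for off, unit in zip(offsets, units):
        off = int(off)
        pieces.append(background[prev:off])
        genome_pos += off - prev
        prev = off
        for s, e, label, strand, attrs in unit.entries:
            if e <= s:
                continue
            placements.append(
                Interval(
                    contig_id=spec.contig_id,
                    start=genome_pos + s,
                    end=genome_pos + e,
                    strand=strand if strand != "." else "+",
                    label=label,
                    attributes=dict(attrs),
                )
            )
        pieces.append(unit.codes)
        genome_pos += unit.codes.shape[0]
    pieces.append(background[prev:])
    genome = np.concatenate(pieces) if pieces else background
    assert genome.shape[0] == spec.genome_length_bp
    placements.sort(key=lambda iv: (iv.start, iv.end))
    record = SeqRecord(spec.contig_id, _seq.decode(genome))
    return GenomeTruth([record], placements, consensi, spec)


def simulate_reads(truth: GenomeTruth, rspec: ReadSimSpec) -> ReadSet:
    """Uniformly sampled fixed-length reads with substitution errors."""
    G = truth.genome_length
    L = rspec.read_length_bp
    if L > G:
        raise ValueError("read length exceeds genome length")
    rng = np.random.default_rng(rspec.seed)
    N = int(round(rspec.coverage * G / L))
    genome = truth.codes
    starts = rng.integers(0, G - L + 1, size=N)
    strands = rng.integers(0, 2, size=N).astype(np.int8)  # 1 = reverse
    reads = genome[starts[:, None] + np.arange(L)[None, :]].copy()
    rev = np.nonzero(strands)[0]
    if rev.size:
        sub = reads[rev][:, ::-1]
        reads[rev] = np.where(sub < 4, 3 - sub.astype(np.int8), sub).astype(np.uint8)
    if rspec.error_rate > 0:
        hit = rng.random(reads.shape) < rspec.error_rate
        shift = rng.integers(1, 4, size=reads.shape).astype(np.uint8)
        reads[hit] = (reads[hit] + shift[hit]) % 4
    return ReadSet(
        reads,
        coverage=N * L / G,
        source_start=starts.astype(np.int64),
        source_strand=strands,
    )


def truth_fractions(truth: GenomeTruth) -> pd.DataFrame:
    """Per-family genome fractions and copy counts from the ledger.

    A fragmented copy (truncated or split by a nested insertion) still
    counts once; its base pairs are the sum of its fragments.
    """
    G = truth.genome_length
    rows: dict[str, dict] = {}
    seen_copies: dict[str, set] = {}
    for iv in truth.placements:
        fam = iv.attributes.get("family")
        if fam is None:
            continue
        row = rows.setdefault(fam, {"bp": 0, "copies": 0, "units": 0})
        row["bp"] += len(iv)
        row["units"] += int(iv.attributes.get("n_units", "1"))
        copy_id = iv.attributes.get("copy", "")
        seen = seen_copies.setdefault(fam, set())
        if copy_id not in seen:
            seen.add(copy_id)
            row["copies"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    if df.empty:
        return pd.DataFrame(columns=["bp", "copies", "units", "fraction"])
    df["fraction"] = df["bp"] / G
    return df.sort_values("bp", ascending=False)


def default_pine_spec(seed: int = 0, genome_length_bp: int = 8_000_000) -> GenomeSpec:
    """A desk-scale genome spec emulating the pine repeat landscape.

    Scaled to ~8 Mb: two young LTR families at ~1.6% and ~1.3% of the
    genome, a 50-bp centromere-like tandem at ~0.27%, telomeric TTTAGGG
    arrays at ~0.24%, six ancient heavily diverged families jointly
    around half the genome, low-complexity tracts, and compact genes
    with a 5:1 pseudogene:gene excess.
    """
    G = genome_length_bp
    scale = G / 8_000_000

    def n(x: float) -> int:
        return max(1, int(round(x * scale)))

    families = [
        RepeatFamilySpec("young-copia-4200", 4200, n(30), divergence=0.03,
                         ltr_length_bp=300),
        RepeatFamilySpec("young-gypsy-4000", 4000, n(26), divergence=0.05,
                         ltr_length_bp=300),
        RepeatFamilySpec("cen-rpt-50", 50, n(432), divergence=0.03,
                         kind="tandem", array_size=108),
        RepeatFamilySpec("tel-rpt", 7, n(2742), divergence=0.0,
                         kind="telomeric", array_size=229),
        RepeatFamilySpec("lowcplx-at", 2, n(3000), divergence=0.0,
                         kind="low_complexity", unit="AT", array_size=150),
    ]
    ancient = [
        ("ancient-1", 5200, 0.22, 182),
        ("ancient-2", 4800, 0.24, 197),
        ("ancient-3", 4400, 0.25, 215),
        ("ancient-4", 3600, 0.26, 263),
        ("ancient-5", 3000, 0.28, 315),
        ("ancient-6", 2600, 0.30, 364),
    ]
    for name, length, div, copies in ancient:
        families.append(
            RepeatFamilySpec(
                name,
                length,
                n(copies),
                divergence=div,
                ltr_length_bp=250,
                fragmentation_prob=0.5,
                nesting_prob=0.08,
            )
        )
    return GenomeSpec(
        genome_length_bp=G,
        base_composition=(0.30, 0.20, 0.20, 0.30),
        families=families,
        gene_count=max(2, n(12)),
        pseudogene_ratio=5,
        seed=seed,
    )
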