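import numpy as np
import pytest

from repeatscape import features
from repeatscape.coverage import CoverageMap
from repeatscape.seqio import Interval

from conftest import mutate_seq, random_seq

# codons whose reverse complements contain stops, so a planted forward
# ORF is not shadowed by a spurious reverse-frame ORF in the cluster
_SAFE_CODONS = ["TTA", "CTA", "TCA"]


def _orf(rng, n_codons):
    body = "".join(
        _SAFE_CODONS[int(rng.integers(0, 3))] for _ in range(n_codons)
    )
    return "ATG" + body + "TAA"


class TestDirectRepeats:
    def test_identical_pair(self, rng):
        ltr = random_seq(rng, 150)
        contig = random_seq(rng, 2000) + ltr + random_seq(rng, 1000) + ltr + random_seq(rng, 2000)
        (p,) = features.find_direct_repeats(contig)
        # maximal-scoring segments may absorb a few matching flank bases
        assert p.identity >= 0.97
        assert p.span_bp == pytest.approx(1300, abs=60)
        assert abs(p.first.start - 2000) <= 10 and abs(p.second.start - 3150) <= 10

    def test_diverged_pair_identity_matches_oracle(self, rng):
        ltr = random_seq(rng, 300)
        ltr2 = mutate_seq(rng, ltr, 0.10)
        planted = np.mean([a == b for a, b in zip(ltr, ltr2)])
        contig = random_seq(rng, 1500) + ltr + random_seq(rng, 2000) + ltr2 + random_seq(rng, 1500)
        (p,) = features.find_direct_repeats(contig)
        assert abs(p.identity - planted) < 0.03

    def test_below_min_len_not_reported(self, rng):
        ltr = random_seq(rng, 80)
        contig = random_seq(rng, 1000) + ltr + random_seq(rng, 1000) + ltr + random_seq(rng, 1000)
        assert features.find_direct_repeats(contig) == []

    def test_span_rule(self, rng):
        ltr = random_seq(rng, 150)
        contig = random_seq(rng, 1000) + ltr + random_seq(rng, 100) + ltr + random_seq(rng, 1000)
        assert features.find_direct_repeats(contig, min_span=500) == []

    def test_noncoding_filter(self, rng):
        ltr = random_seq(rng, 150)
        contig = random_seq(rng, 1000) + ltr + random_seq(rng, 1000) + ltr + random_seq(rng, 1000)
        exon = [Interval("contig", 1050, 1120, "+", "exon")]
        assert features.find_direct_repeats(contig, annotations=exon) == []
        assert len(features.find_direct_repeats(contig)) == 1

    def test_no_false_pairs_on_random_contigs(self):
        for s in range(3):
            rng = np.random.default_rng(500 + s)
            assert features.find_direct_repeats(random_seq(rng, 100_000)) == []

    def test_recall_of_planted_pairs_up_to_20pct_divergence(self, rng):
        found = 0
        n = 12
        for i in range(n):
            div = 0.20 * i / (n - 1)
            ltr = random_seq(rng, 300)
            contig = (
                random_seq(rng, 800)
                + ltr
                + random_seq(rng, 1500)
                + mutate_seq(rng, ltr, 2 * div)  # pairwise divergence ~2x per-copy
                + random_seq(rng, 800)
            )
            found += bool(features.find_direct_repeats(contig))
        assert found >= round(0.9 * n)


class TestTandemRepeats:
    def test_exact_periodicity(self, rng):
        contig = random_seq(rng, 500) + "ACGTG" * 30 + random_seq(rng, 500)
        (t,) = features.find_tandem_repeats(contig)
        assert t.period_bp == 5
        assert t.copy_number == pytest.approx(30, rel=0.1)
        assert t.consensus_unit in "ACGTG" * 2

    def test_unit_above_range_not_reported(self, rng):
        unit = random_seq(rng, 201)
        contig = random_seq(rng, 500) + unit * 5 + random_seq(rng, 500)
        assert features.find_tandem_repeats(contig) == []

    def test_diverged_50bp_array(self, rng):
        unit = random_seq(rng, 50)
        arr = "".join(mutate_seq(rng, unit, 0.05) for _ in range(40))
        contig = random_seq(rng, 1000) + arr + random_seq(rng, 1000)
        hits = features.find_tandem_repeats(contig)
        assert len(hits) == 1 and hits[0].period_bp == 50
        assert hits[0].percent_matches >= 0.8

    def test_period_minimality(self, rng):
        contig = random_seq(rng, 300) + "ACGTG" * 40 + random_seq(rng, 300)
        periods = [t.period_bp for t in features.find_tandem_repeats(contig)]
        assert periods == [5]  # not also reported at 10, 15, ...


class TestSimpleRepeats:
    def test_poly_a_tract(self, rng):
        contig = random_seq(rng, 1000) + "A" * 100 + random_seq(rng, 1000)
        hits = features.find_simple_repeats(contig)
        assert any(iv.start <= 1000 and iv.end >= 1100 for iv in hits)

    def test_dinucleotide_microsatellite(self, rng):
        contig = random_seq(rng, 1000) + "AT" * 50 + random_seq(rng, 1000)
        hits = features.find_simple_repeats(contig)
        covering = [iv for iv in hits if iv.start <= 1000 and iv.end >= 1098]
        assert covering and covering[0].attributes["class"] in ("di", "low_entropy")

    def test_random_sequence_yields_nothing(self):
        rng = np.random.default_rng(600)
        assert features.find_simple_repeats(random_seq(rng, 10_000)) == []


class TestOrfElements:
    def test_planted_intergenic_orf_reported(self, rng):
        orf = _orf(rng, 98)  # 300 bp
        contig = random_seq(rng, 2000) + orf + random_seq(rng, 2000)
        hits = features.find_orf_elements(contig)
        # the cluster representative must cover the planted ORF (a longer
        # overlapping ORF in another frame may legitimately represent it)
        assert any(o.interval.start < 2300 and o.interval.end > 2000 for o in hits)

    def test_short_orf_not_reported(self, rng):
        orf = _orf(rng, 48)  # 150 bp
        contig = random_seq(rng, 500) + orf + random_seq(rng, 500)
        hits = features.find_orf_elements(contig)
        assert not any(o.interval.start == 500 for o in hits)

    def test_orf_inside_gene_excluded(self, rng):
        orf = _orf(rng, 98)
        contig = random_seq(rng, 2000) + orf + random_seq(rng, 2000)
        gene = [Interval("contig", 1900, 2500, "+", "gene")]
        hits = features.find_orf_elements(contig, gene_annotations=gene)
        assert not any(o.interval.start == 2000 for o in hits)

    def test_orf_properties(self, rng):
        orf = _orf(rng, 120)
        contig = random_seq(rng, 1500) + orf + random_seq(rng, 1500)
        for o in features.find_orf_elements(contig):
            assert o.length_bp % 3 == 0 and o.length_bp >= 240

    def test_repetitive_coverage_flag(self, rng):
        orf = _orf(rng, 98)
        contig = random_seq(rng, 600) + orf + random_seq(rng, 600)
        rep = [
            o for o in features.find_orf_elements(contig)
            if o.interval.start < 900 and o.interval.end > 600
        ]
        assert rep
        depth = np.zeros(len(contig), int)
        depth[rep[0].interval.start : rep[0].interval.end] = 3
        cm = CoverageMap("contig", 0.75, depth, 0.036)
        hits = features.find_orf_elements(contig, covmap=cm)
        flagged = [
            o for o in hits
            if o.interval.start == rep[0].interval.start
        ]
        assert flagged and flagged[0].overlaps_repetitive_coverage is True
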