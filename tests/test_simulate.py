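import numpy as np
import pytest
from scipy import stats

from repeatscape import _seq, simulate
from repeatscape.simulate import GenomeSpec, ReadSimSpec, RepeatFamilySpec


def _full_copies(truth, family):
    return [
        iv
        for iv in truth.placements
        if iv.attributes.get("family") == family
        and "fragment" not in iv.attributes
        and "nested_in" not in iv.attributes
    ]


class TestSimulateGenome:
    def test_zero_divergence_fraction_and_identity(self):
        spec = GenomeSpec(
            genome_length_bp=1_000_000,
            families=[RepeatFamilySpec("f", 400, 100, divergence=0.0)],
            seed=1,
        )
        truth = simulate.simulate_genome(spec)
        tf = simulate.truth_fractions(truth)
        assert tf.loc["f", "fraction"] == pytest.approx(100 * 400 / 1e6)
        assert all(
            float(iv.attributes["identity"]) == 1.0 for iv in _full_copies(truth, "f")
        )

    def test_divergence_recovered_from_ledger(self):
        """Mean per-copy identity sits within 3 binomial SE of 1 - d."""
        d, copies, length = 0.05, 200, 500
        spec = GenomeSpec(
            genome_length_bp=2_000_000,
            families=[RepeatFamilySpec("f", length, copies, divergence=d)],
            seed=2,
        )
        truth = simulate.simulate_genome(spec)
        idents = [float(iv.attributes["identity"]) for iv in _full_copies(truth, "f")]
        se = np.sqrt(d * (1 - d) / (copies * length))
        assert abs(np.mean(idents) - (1 - d)) < 3 * se
        # identities are also recomputable from the stored consensus
        consensus = _seq.encode(truth.consensi["f"])
        genome = truth.codes
        iv = _full_copies(truth, "f")[0]
        copy = genome[iv.start : iv.end]
        if iv.strand == "-":
            copy = _seq.revcomp(copy)
        ident = np.count_nonzero(copy == consensus) / length
        assert ident == pytest.approx(float(iv.attributes["identity"]), abs=1e-4)

    def test_placements_in_bounds_and_non_overlapping(self):
        spec = simulate.default_pine_spec(3, genome_length_bp=2_000_000)
        truth = simulate.simulate_genome(spec)
        assert truth.genome_length == 2_000_000
        prev_end = 0
        for iv in sorted(truth.placements, key=lambda x: x.start):
            if iv.label == "exon":  # exons nest inside their gene span
                continue
            assert 0 <= iv.start < iv.end <= truth.genome_length
            assert iv.start >= prev_end
            prev_end = iv.end

    def test_overfilled_genome_rejected(self):
        spec = GenomeSpec(
            genome_length_bp=10_000,
            families=[RepeatFamilySpec("f", 400, 100, divergence=0.0)],
            seed=1,
        )
        with pytest.raises(ValueError):
            simulate.simulate_genome(spec)

    def test_determinism(self):
        spec = simulate.default_pine_spec(7, genome_length_bp=1_000_000)
        t1 = simulate.simulate_genome(spec)
        t2 = simulate.simulate_genome(simulate.default_pine_spec(7, genome_length_bp=1_000_000))
        assert t1.records[0].sequence == t2.records[0].sequence
        assert len(t1.placements) == len(t2.placements)
        r1 = simulate.simulate_reads(t1, ReadSimSpec(60, 0.036, 0.01, seed=9))
        r2 = simulate.simulate_reads(t2, ReadSimSpec(60, 0.036, 0.01, seed=9))
        assert np.array_equal(r1.codes, r2.codes)


class TestTruthFractions:
    def test_tandem_array_fraction(self):
        spec = GenomeSpec(
            genome_length_bp=1_000_000,
            families=[RepeatFamilySpec("cen", 50, 100, kind="tandem", array_size=100)],
            seed=4,
        )
        tf = simulate.truth_fractions(simulate.simulate_genome(spec))
        assert tf.loc["cen", "fraction"] == pytest.approx(0.005)
        assert tf.loc["cen", "units"] == 100

    def test_empty_family_list(self):
        truth = simulate.simulate_genome(GenomeSpec(genome_length_bp=50_000, seed=5))
        assert simulate.truth_fractions(truth).empty

    def test_fractions_bounded_by_one(self):
        spec = simulate.default_pine_spec(6, genome_length_bp=2_000_000)
        tf = simulate.truth_fractions(simulate.simulate_genome(spec))
        assert 0 < tf["fraction"].sum() <= 1.0


class TestSimulateReads:
    def test_pool_size_formula(self):
        truth = simulate.simulate_genome(GenomeSpec(genome_length_bp=1_000_000, seed=1))
        reads = simulate.simulate_reads(truth, ReadSimSpec(60, 0.036, seed=2))
        assert reads.count == round(0.036 * 1_000_000 / 60) == 600
        assert reads.coverage == pytest.approx(600 * 60 / 1_000_000)

    def test_error_free_reads_are_genome_substrings(self):
        truth = simulate.simulate_genome(GenomeSpec(genome_length_bp=100_000, seed=3))
        reads = simulate.simulate_reads(truth, ReadSimSpec(40, 0.05, 0.0, seed=4))
        genome = truth.codes
        for i in range(reads.count):
            src = genome[reads.source_start[i] : reads.source_start[i] + 40]
            if reads.source_strand[i]:
                src = _seq.revcomp(src)
            assert np.array_equal(reads.codes[i], src)

    def test_error_rate_recovered(self):
        truth = simulate.simulate_genome(GenomeSpec(genome_length_bp=500_000, seed=5))
        n, L, e = 10_000, 60, 0.01
        reads = simulate.simulate_reads(truth, ReadSimSpec(L, n * L / 500_000, e, seed=6))
        genome = truth.codes
        total = 0
        for i in range(reads.count):
            src = genome[reads.source_start[i] : reads.source_start[i] + L]
            if reads.source_strand[i]:
                src = _seq.revcomp(src)
            total += int(np.count_nonzero(reads.codes[i] != src))
        expected = reads.count * L * e
        se = np.sqrt(reads.count * L * e * (1 - e))
        assert abs(total - expected) < 3 * se

    def test_read_starts_uniform(self):
        truth = simulate.simulate_genome(GenomeSpec(genome_length_bp=200_000, seed=7))
        reads = simulate.simulate_reads(truth, ReadSimSpec(60, 30.0, 0.0, seed=8))
        assert reads.count == 100_000
        counts, _ = np.histogram(reads.source_start, bins=20)
        assert stats.chisquare(counts).pvalue > 0.001


class TestDefaultSpec:
    def test_headline_family_fractions(self):
        truth = simulate.simulate_genome(simulate.default_pine_spec(11, genome_length_bp=2_000_000))
        tf = simulate.truth_fractions(truth)
        assert tf.loc["young-copia-4200", "fraction"] == pytest.approx(0.016, rel=0.10)
        assert tf.loc["young-gypsy-4000", "fraction"] == pytest.approx(0.013, rel=0.10)
        assert tf.loc["cen-rpt-50", "fraction"] == pytest.approx(0.0027, rel=0.10)
        assert tf.loc["tel-rpt", "fraction"] == pytest.approx(0.0024, rel=0.10)
        ancient = tf.loc[[f"ancient-{i}" for i in range(1, 7)], "fraction"].sum()
        assert 0.4 < ancient < 0.7

    def test_pseudogene_gene_ratio(self):
        truth = simulate.simulate_genome(simulate.default_pine_spec(12, genome_length_bp=2_000_000))
        genes = {iv.attributes["copy"] for iv in truth.placements if iv.label == "gene"}
        pseudo = {iv.attributes["copy"] for iv in truth.placements if iv.label == "pseudogene"}
        assert len(pseudo) == 5 * len(genes) > 0
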