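import numpy as np
import pytest

from repeatscape import assemble, simulate
from repeatscape.assemble import AssemblyParams, NoSeedError
from repeatscape.seqio import ReadSet
from repeatscape.simulate import GenomeSpec, ReadSimSpec, RepeatFamilySpec

from conftest import random_seq


class TestSelectSeed:
    def test_seed_comes_from_the_repeated_element(self, rng):
        element = random_seq(rng, 200)
        reads = ReadSet.from_strings(
            [element[i : i + 40] for i in range(0, 160, 5)] * 4
        )
        seed = assemble.select_seed(reads, AssemblyParams())
        from repeatscape._seq import revcomp_str

        assert seed in element or revcomp_str(seed) in element

    def test_poly_a_pool_fails_entropy_filter(self):
        reads = ReadSet.from_strings(["A" * 40] * 50)
        with pytest.raises(NoSeedError):
            assemble.select_seed(reads, AssemblyParams())

    def test_seed_tracks_the_more_abundant_family(self, rng):
        """Across seeded replicates the seed belongs to the 2:1 family."""
        famA, famB = random_seq(rng, 600), random_seq(rng, 600)
        wins = 0
        n_rep = 10
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            seqs = []
            for fam, n in ((famA, 120), (famB, 60)):
                starts = r.integers(0, len(fam) - 40, size=n)
                seqs.extend(fam[s : s + 40] for s in starts)
            order = r.permutation(len(seqs))
            reads = ReadSet.from_strings([seqs[i] for i in order])
            seed = assemble.select_seed(reads, AssemblyParams())
            from repeatscape._seq import revcomp_str

            wins += seed in famA or revcomp_str(seed) in famA
        assert wins >= n_rep - 1


class TestExtendConsensus:
    def test_tiling_identical_copies_reconstructs_element(self, rng):
        element = random_seq(rng, 200)
        reads = ReadSet.from_strings(
            [element[i : i + 40] for i in range(0, 161, 5)] * 6
        )
        params = AssemblyParams()
        seed = assemble.select_seed(reads, params)
        cons = assemble.extend_consensus(reads, seed, params)
        from repeatscape._seq import revcomp_str

        assert cons.sequence in element or revcomp_str(cons.sequence) in element
        assert len(cons) >= 150

    def test_seed_absent_rejected(self, rng):
        reads = ReadSet.from_strings([random_seq(rng, 40) for _ in range(30)])
        with pytest.raises(ValueError):
            assemble.extend_consensus(reads, "ACGT" * 4, AssemblyParams())

    def test_telomeric_reads_terminate_with_period_7(self):
        tel = "TTTAGGG" * 12
        reads = ReadSet.from_strings([tel[i : i + 40] for i in range(0, 44)] * 3)
        params = AssemblyParams()
        seed = assemble.select_seed(reads, params, min_count=2)
        cons = assemble.extend_consensus(reads, seed, params)
        assert cons.structure["tandem_period"] == 7

    def test_determinism(self):
        spec = GenomeSpec(
            genome_length_bp=500_000,
            families=[RepeatFamilySpec("f", 1000, 150, divergence=0.03)],
            seed=21,
        )
        truth = simulate.simulate_genome(spec)
        reads = simulate.simulate_reads(truth, ReadSimSpec(40, 0.1, 0.01, seed=22))
        params = AssemblyParams()
        seed = assemble.select_seed(reads, params)
        c1 = assemble.extend_consensus(reads, seed, params)
        c2 = assemble.extend_consensus(reads, seed, params)
        assert c1.sequence == c2.sequence
        assert c1.supporting_read_count == c2.supporting_read_count


class TestDetectStructure:
    def test_identical_terminal_repeats(self, rng):
        ltr = random_seq(rng, 300)
        element = ltr + random_seq(rng, 1400) + ltr
        st = assemble.detect_structure(element)
        s1, e1, s2, e2, ident = st["ltr_pair"]
        assert ident == 1.0
        assert e1 - s1 >= 300 and e2 == len(element)

    def test_exact_periodicity(self):
        st = assemble.detect_structure("ACGTG" * 30)
        assert st["tandem_period"] == 5

    def test_diverged_terminal_repeats_identity(self, rng):
        from conftest import mutate_seq

        ltr = random_seq(rng, 300)
        element = ltr + random_seq(rng, 1400) + mutate_seq(rng, ltr, 0.10)
        planted_ident = np.mean(
            [a == b for a, b in zip(element[:300], element[-300:])]
        )
        st = assemble.detect_structure(element)
        assert st["ltr_pair"] is not None
        assert abs(st["ltr_pair"][4] - planted_ident) < 0.03


class TestAssembleTopRepeats:
    def test_pure_background_yields_nothing(self):
        truth = simulate.simulate_genome(GenomeSpec(genome_length_bp=400_000, seed=23))
        reads = simulate.simulate_reads(truth, ReadSimSpec(40, 0.03, 0.0, seed=24))
        assert assemble.assemble_top_repeats(reads, AssemblyParams()) == []

    def test_two_families_ranked_and_pool_shrinks(self):
        spec = GenomeSpec(
            genome_length_bp=1_000_000,
            families=[
                RepeatFamilySpec("big", 800, 150, divergence=0.02),
                RepeatFamilySpec("small", 800, 60, divergence=0.02),
            ],
            seed=25,
        )
        truth = simulate.simulate_genome(spec)
        reads = simulate.simulate_reads(truth, ReadSimSpec(40, 0.15, 0.005, seed=26))
        out = assemble.assemble_top_repeats(reads, AssemblyParams(max_elements=2))
        assert len(out) == 2
        assert out[0].supporting_read_count > out[1].supporting_read_count
        # the stronger element must belong to the 150-copy family
        from repeatscape import align

        hits = align.find_hits(
            out[0].sequence[:60], truth.consensi["big"], min_identity=0.9
        )
        assert hits


class TestTiledReference:
    def test_non_tandem_passthrough(self):
        cons = assemble.RepeatConsensus("e", "ACGT" * 50, 10, np.ones(200))
        assert assemble.tiled_reference(cons, 40) == cons.sequence

    def test_tandem_tiled_past_read_length(self):
        cons = assemble.RepeatConsensus(
            "t", "ACGTG" * 20, 10, np.ones(100),
            structure={"ltr_pair": None, "tandem_period": 5},
        )
        ref = assemble.tiled_reference(cons, 40)
        assert len(ref) >= 45 and set(ref[i : i + 5] for i in range(0, 40, 5)) == {"ACGTG"}
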