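"""Generator correctness: determinism, planted-feature ledgers, dose model."""

import numpy as np
import pytest

from viriscape import simgen
from viriscape._seqcodes import revcomp


def gc_fraction(seq):
    return (seq.count("G") + seq.count("C")) / len(seq)


class TestRandomGenome:
    def test_length_and_gc(self):
        g = simgen.make_random_genome({"c": 10_000}, gc=0.5, seed=1)
        assert len(g["c"]) == 10_000
        assert 0.47 <= gc_fraction(g["c"]) <= 0.53

    def test_deterministic_for_fixed_seed(self):
        a = simgen.make_random_genome({"c": 5_000}, gc=0.4, seed=3)
        b = simgen.make_random_genome({"c": 5_000}, gc=0.4, seed=3)
        assert a["c"] == b["c"]

    def test_gc_zero_is_all_at(self):
        g = simgen.make_random_genome({"c": 2_000}, gc=0.0, seed=1)
        assert set(g["c"]) <= {"A", "T"}

    @pytest.mark.parametrize("length", [0, -5, 500])
    def test_bad_lengths_rejected(self, length):
        with pytest.raises(ValueError):
            simgen.make_random_genome({"c": length}, seed=1)


class TestMutateSequence:
    def test_zero_divergence_is_identity(self, small_genome):
        seq = small_genome["chrB"][:2_000]
        assert simgen.mutate_sequence(seq, 0.0, seed=1) == seq

    def test_mismatch_fraction_matches_binomial_expectation(self):
        # binomial oracle: se = sqrt(0.1*0.9/10000) ~ 0.003
        g = simgen.make_random_genome({"c": 10_000}, seed=5)
        m = simgen.mutate_sequence(g["c"], 0.10, seed=6)
        mism = sum(a != b for a, b in zip(g["c"], m)) / 10_000
        assert abs(mism - 0.10) <= 3 * np.sqrt(0.1 * 0.9 / 10_000)
        assert len(m) == len(g["c"])

    @pytest.mark.parametrize("div", [-0.01, 0.41, 1.0])
    def test_out_of_range_divergence_rejected(self, div):
        with pytest.raises(ValueError):
            simgen.mutate_sequence("ACGT" * 100, div, seed=1)


class TestPlantRepeats:
    def test_tandem_arrays_recorded_exactly(self):
        g = simgen.make_random_genome({"c": 100_000}, seed=10)
        fam = simgen.RepeatFamilySpec(
            "itr1", "ITR", consensus_length=516, mode="tandem", monomer_length=172
        )
        g2 = simgen.plant_repeats(g, fam, 5, array_length_range=(5_500, 5_500), seed=11)
        reps = g2.truth.planted_repeats
        assert len(reps) == 5
        assert np.mean([r.end - r.start for r in reps]) == 5_500
        # ledger names each insertion exactly: extracted sequence is the
        # tiled monomer (divergence 0 here)
        for r in reps:
            extracted = g2[r.chrom][r.start : r.end]
            expected = (fam.monomer * 33)[:5_500]
            assert extracted == expected

    def test_zero_copies_is_identity(self, small_genome):
        fam = simgen.RepeatFamilySpec("f", "LTR", consensus_length=100)
        g2 = simgen.plant_repeats(small_genome, fam, 0, seed=1)
        assert g2.seqs == small_genome.seqs
        assert g2.truth.planted_repeats == []

    def test_divergences_within_requested_range(self):
        g = simgen.make_random_genome({"c": 200_000}, seed=12)
        fam = simgen.RepeatFamilySpec("f", "LINE", consensus_length=300)
        g2 = simgen.plant_repeats(g, fam, 30, divergence_range=(0.08, 0.10), seed=13)
        assert all(0.08 <= r.divergence <= 0.10 for r in g2.truth.planted_repeats)

    def test_total_length_conserved(self):
        g = simgen.make_random_genome({"c": 50_000}, seed=14)
        fam = simgen.RepeatFamilySpec("f", "LTR", consensus_length=250)
        g2 = simgen.plant_repeats(g, fam, 10, seed=15)
        assert g2.total_length() == g.total_length() + 10 * 250

    def test_genome_too_small_rejected(self):
        g = simgen.make_random_genome({"c": 1_000}, seed=16)
        fam = simgen.RepeatFamilySpec("f", "LTR", consensus_length=100)
        with pytest.raises(ValueError, match="too small"):
            simgen.plant_repeats(g, fam, 2_000, seed=17)

    def test_tandem_monomer_too_short_rejected(self):
        with pytest.raises(ValueError):
            simgen.RepeatFamilySpec("f", "ITR", mode="tandem", monomer_length=5)


class TestApplyInversions:
    def test_single_inversion_reverse_complements(self):
        g = simgen.make_random_genome({"c": 30_000}, seed=20)
        g2 = simgen.apply_inversions(g, [("c", 10_000, 20_000)])
        assert g2["c"][10_000:20_000] == revcomp(g["c"][10_000:20_000])
        assert g2["c"][:10_000] == g["c"][:10_000]
        assert g2["c"][20_000:] == g["c"][20_000:]
        assert g2.truth.breakpoints() == [("c", 10_000), ("c", 20_000)]

    def test_empty_spec_is_identity(self, small_genome):
        g2 = simgen.apply_inversions(small_genome, [])
        assert g2.seqs == small_genome.seqs

    def test_overlapping_intervals_rejected(self):
        g = simgen.make_random_genome({"c": 30_000}, seed=21)
        with pytest.raises(ValueError, match="overlap"):
            simgen.apply_inversions(g, [("c", 1_000, 20_000), ("c", 5_000, 10_000)])

    def test_out_of_bounds_rejected(self):
        g = simgen.make_random_genome({"c": 5_000}, seed=22)
        with pytest.raises(ValueError):
            simgen.apply_inversions(g, [("c", 4_000, 9_000)])

    def test_flank_element_planted_at_each_breakpoint(self):
        g = simgen.make_random_genome({"c": 50_000}, seed=23)
        fam = simgen.RepeatFamilySpec("mite", "DNA-TIR", consensus_length=200)
        g2 = simgen.apply_inversions(g, [("c", 10_000, 30_000)], flank_element=fam, seed=24)
        reps = sorted(g2.truth.planted_repeats, key=lambda r: r.start)
        assert len(reps) == 2
        (c, s, e), = g2.truth.planted_inversions
        # one copy ends at the (shifted) inversion start, one starts at its end
        assert reps[0].end == s
        assert reps[1].start == e
        assert g2.total_length() == g.total_length() + 2 * 200


class TestSimulateReads:
    def test_female_has_no_y_reads_and_double_x_depth(self):
        lengths = {"a1": 20_000, "x1": 20_000, "y1": 20_000}
        g = simgen.make_random_genome(
            lengths, seed=30, contig_class={"a1": "A", "x1": "X", "y1": "Y"}
        )
        male, female = simgen.simulate_sex_reads(g, depth=30, read_length=100, seed=31)
        covf = female.coverage_table(g.lengths()).set_index("contig")["mean_depth"]
        covm = male.coverage_table(g.lengths()).set_index("contig")["mean_depth"]
        assert covf["y1"] == 0.0
        assert abs(covf["x1"] - 60.0) < 1.0  # dose 2: Poisson 3-se band is ~0.5x
        assert abs(covm["a1"] - 30.0) < 1.0

    def test_error_free_reads_are_exact_substrings(self, small_genome):
        rs = simgen.simulate_reads(small_genome, depth=2, read_length=80, seed=32)
        contig, starts, codes = rs.chunks[0]
        from viriscape._seqcodes import decode

        for i in range(0, starts.size, max(1, starts.size // 20)):
            s = int(starts[i])
            assert decode(codes[i]) == small_genome[contig][s : s + 80]

    def test_short_contig_skipped_with_warning(self):
        g = simgen.make_random_genome({"c": 1_000}, seed=33)
        with pytest.warns(UserWarning, match="shorter than read length"):
            rs = simgen.simulate_reads(g, depth=5, read_length=2_000, seed=34)
        assert rs.n_reads == 0

    def test_fastq_roundtrip_deterministic(self, tmp_path, small_genome):
        rs1 = simgen.simulate_reads(small_genome, depth=0.5, read_length=60, seed=35)
        rs2 = simgen.simulate_reads(small_genome, depth=0.5, read_length=60, seed=35)
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        rs1.write_fastq(p1)
        rs2.write_fastq(p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestGenotypePanel:
    def test_pi_target_zero_all_monomorphic(self):
        table, _ = simgen.simulate_genotype_panel(6, 1_000, 0.0, seed=40)
        assert (table["allele_count_alt"] == 0).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            simgen.simulate_genotype_panel(1, 100, 0.01, seed=41)

    def test_full_missingness_rejected(self):
        with pytest.raises(ValueError):
            simgen.simulate_genotype_panel(5, 100, 0.01, missing_rate=1.0, seed=42)

    def test_counts_consistent(self):
        table, _ = simgen.simulate_genotype_panel(8, 2_000, 0.05, missing_rate=0.2, seed=43)
        assert (
            table["allele_count_ref"] + table["allele_count_alt"] == table["n_called"]
        ).all()
        assert (table["n_called"] <= 8).all()


def test_truth_survives_fasta_roundtrip(tmp_path, small_genome):
    p = tmp_path / "g.fasta"
    simgen.write_fasta(small_genome, p)
    back = simgen.read_fasta(p)
    assert back.seqs == small_genome.seqs
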