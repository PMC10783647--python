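"""Family clustering, cross-genome search, novelty and insertion calling."""

import numpy as np
import pytest

from viriscape import repeat_dynamics as rd
from viriscape import repeatscape, simgen
from viriscape._seqcodes import revcomp
from viriscape.repeatscape import RepeatAnnotation


def make_consensus(length, seed):
    fam = simgen.RepeatFamilySpec(f"c{seed}", "Unknown", consensus_length=length)
    return fam.realize(seed=seed)


def ann(chrom, start, end, family, div=5.0, subclass="Unknown"):
    return RepeatAnnotation(chrom, start, end, family, subclass, div)


class TestClusterFamilies:
    def test_identical_consensi_cluster_together(self):
        cons = make_consensus(400, 1)
        libs = {
            "A": [rd.RepeatFamily("famA", cons, "A")],
            "B": [rd.RepeatFamily("famB", cons, "B")],
        }
        clusters, singles = rd.cluster_families(libs)
        assert len(clusters) == 1 and singles == []

    def test_unrelated_family_is_singleton(self):
        libs = {
            "A": [rd.RepeatFamily("famA", make_consensus(400, 2), "A")],
            "B": [rd.RepeatFamily("famB", make_consensus(400, 3), "B")],
        }
        _, singles = rd.cluster_families(libs)
        assert sorted(f.name for f in singles) == ["famA", "famB"]

    def test_mutated_copies_cluster_across_three_libraries(self):
        cons = make_consensus(600, 4)
        libs = {
            g: [rd.RepeatFamily(f"fam{g}", simgen.mutate_sequence(cons, 0.05, seed=i), g)]
            for i, g in enumerate(["A", "B", "C"])
        }
        # oracle: direct pairwise identity of the mutated copies stays >= 90%
        pairs = [(libs["A"][0], libs["B"][0]), (libs["A"][0], libs["C"][0])]
        for x, y in pairs:
            assert rd._pair_identity(x.consensus, y.consensus) >= 90.0
        clusters, singles = rd.cluster_families(libs)
        assert len(clusters) == 1 and len(clusters[0]) == 3 and singles == []

    def test_duplicate_names_get_library_prefix(self):
        cons1, cons2 = make_consensus(300, 5), make_consensus(300, 6)
        libs = {
            "A": [rd.RepeatFamily("fam", cons1, "A")],
            "B": [rd.RepeatFamily("fam", cons2, "B")],
        }
        _, singles = rd.cluster_families(libs)
        assert {f.name for f in singles} == {"fam", "B:fam"}

    def test_reverse_complement_counts_as_identity(self):
        cons = make_consensus(400, 7)
        libs = {
            "A": [rd.RepeatFamily("f1", cons, "A")],
            "B": [rd.RepeatFamily("f2", revcomp(cons), "B")],
        }
        clusters, singles = rd.cluster_families(libs)
        assert len(clusters) == 1 and singles == []


class TestCrossGenomeSearch:
    def test_verbatim_copy_found_at_full_length(self):
        cons = make_consensus(500, 10)
        g = simgen.make_random_genome({"c": 50_000}, seed=11)
        g2 = simgen.Genome({"c": g["c"][:20_000] + cons + g["c"][20_000:]})
        (hit,) = rd.cross_genome_search(cons, g2, family_name="f")
        assert (hit.start, hit.end) == (20_000, 20_500)
        assert hit.pct_identity == 100.0

    def test_no_shared_seed_no_hits(self):
        cons = "AT" * 150  # AT-only query vs GC-rich genome
        g = simgen.make_random_genome({"c": 10_000}, gc=0.9, seed=12)
        assert rd.cross_genome_search(cons, g, family_name="f") == []

    def test_diverged_copy_identity_near_planted_divergence(self):
        cons = make_consensus(600, 13)
        g = simgen.make_random_genome({"c": 40_000}, seed=14)
        copy = simgen.mutate_sequence(cons, 0.15, seed=15)
        g2 = simgen.Genome({"c": g["c"][:10_000] + copy + g["c"][10_000:]})
        hits = rd.cross_genome_search(cons, g2, min_identity=70.0, family_name="f")
        assert len(hits) == 1
        # binomial oracle: se of mismatch count = sqrt(600*0.15*0.85) ~ 8.7;
        # edit distance may undercut raw mismatches slightly via gaps
        se_pct = 100 * np.sqrt(600 * 0.15 * 0.85) / 600
        assert abs(hits[0].pct_identity - 85.0) <= 3 * se_pct

    def test_minus_strand_copy_found(self):
        cons = make_consensus(400, 16)
        g = simgen.make_random_genome({"c": 30_000}, seed=17)
        g2 = simgen.Genome({"c": g["c"][:5_000] + revcomp(cons) + g["c"][5_000:]})
        (hit,) = rd.cross_genome_search(cons, g2, family_name="f")
        assert (hit.start, hit.end, hit.pct_identity) == (5_000, 5_400, 100.0)


class TestIsNovel:
    def _own(self, bp=6_000, div=5.0, name="fam"):
        return [ann("c", i * 1_000, i * 1_000 + bp // 6, name, div) for i in range(6)]

    def test_significant_cross_hit_blocks_novelty(self):
        hits = {"B": [rd.GenomeHit("fam", "c", 0, 150, 85.0)], "C": []}
        verdict, reasons = rd.is_novel("fam", self._own(), hits)
        assert not verdict and any("significant hit" in r for r in reasons)

    def test_low_abundance_blocks_novelty(self):
        verdict, reasons = rd.is_novel("fam", self._own(bp=3_000), {"B": [], "C": []})
        assert not verdict and any("abundance" in r for r in reasons)

    def test_high_divergence_blocks_novelty(self):
        verdict, reasons = rd.is_novel("fam", self._own(div=15.0), {"B": [], "C": []})
        assert not verdict and any("divergence" in r for r in reasons)

    def test_qualifying_singleton_is_novel(self):
        verdict, reasons = rd.is_novel("fam", self._own(), {"B": [], "C": []})
        assert verdict

    def test_short_or_weak_hits_ignored(self):
        hits = {
            "B": [rd.GenomeHit("fam", "c", 0, 90, 95.0)],  # < 100 bp
            "C": [rd.GenomeHit("fam", "c", 0, 300, 75.0)],  # < 80% identity
        }
        verdict, _ = rd.is_novel("fam", self._own(), hits)
        assert verdict

    def test_verdict_invariant_to_annotation_order(self, rng):
        own = self._own()
        shuffled = list(own)
        rng.shuffle(shuffled)
        assert rd.is_novel("fam", own, {"B": []}) == rd.is_novel("fam", shuffled, {"B": []})


class TestIsolationAndFlanks:
    def _loci(self):
        import pandas as pd

        return pd.DataFrame(
            [{"chrom": "c", "start": 10_000, "end": 11_500, "length": 1_500}]
        )

    def test_nearby_foreign_repeat_excludes_locus(self):
        others = [ann("c", 9_400, 9_600, "other")]
        kept = rd.eligible_isolated_loci(self._loci(), others, "itr", isolation=1_000)
        assert len(kept) == 0

    def test_isolated_locus_kept(self):
        others = [ann("c", 20_000, 20_500, "other")]
        kept = rd.eligible_isolated_loci(self._loci(), others, "itr", isolation=1_000)
        assert len(kept) == 1

    def test_own_family_neighbors_do_not_exclude(self):
        others = [ann("c", 9_400, 9_600, "itr")]
        kept = rd.eligible_isolated_loci(self._loci(), others, "itr", isolation=1_000)
        assert len(kept) == 1

    def test_flank_signature_coordinates(self, small_genome):
        probe = rd.flank_signature(small_genome, ("chrA", 1_000, 2_000), flank=100)
        assert probe == small_genome["chrA"][900:1_000] + small_genome["chrA"][2_000:2_100]
        assert len(probe) == 200

    def test_insufficient_flank_rejected(self, small_genome):
        with pytest.raises(ValueError, match="flank"):
            rd.flank_signature(small_genome, ("chrA", 50, 500), flank=100)


class TestSiteIntact:
    def _setup(self):
        g = simgen.make_random_genome({"c": 60_000}, seed=20)
        insert = make_consensus(1_500, 21)
        carrier = simgen.Genome({"c": g["c"][:30_000] + insert + g["c"][30_000:]})
        probe = rd.flank_signature(carrier, ("c", 30_000, 31_500), flank=100)
        return g, carrier, probe

    def test_empty_site_is_intact(self):
        empty, _, probe = self._setup()
        assert rd.site_intact(probe, empty) == "intact"

    def test_carrier_genome_not_intact(self):
        _, carrier, probe = self._setup()
        assert rd.site_intact(probe, carrier) == "not_intact"

    def test_duplicated_site_ambiguous(self):
        empty, _, probe = self._setup()
        dup = simgen.Genome({"c": empty["c"], "c2": "T" * 500 + empty["c"][29_000:31_000] + "A" * 500})
        assert rd.site_intact(probe, dup) == "ambiguous"


class TestPolymorphicCalls:
    def _trio(self, with_insertion=True):
        base = simgen.make_random_genome({"c": 80_000}, seed=30)
        itr = simgen.RepeatFamilySpec(
            "172TR", "ITR", consensus_length=516, mode="tandem", monomer_length=172
        )
        shared = simgen.plant_repeats(
            base, itr, 1, array_length_range=(1_000, 1_000), seed=31
        )
        genomes = {"A": shared.copy(), "B": shared.copy(), "C": shared.copy()}
        if with_insertion:
            genomes["A"] = simgen.plant_repeats(
                genomes["A"], itr, 1, array_length_range=(1_500, 1_500), seed=32
            )
        annots = {
            n: repeatscape.annotations_from_truth(g.truth) for n, g in genomes.items()
        }
        return genomes, annots

    def test_private_array_called_exactly_once(self):
        genomes, annots = self._trio()
        calls = rd.call_polymorphic_insertions(genomes, annots, "172TR")
        called = calls[calls["called"]]
        assert len(called) == 1
        assert called.iloc[0]["focal_genome"] == "A"
        assert called.iloc[0]["array_length"] == 1_500

    def test_identical_trio_no_calls(self):
        genomes, annots = self._trio(with_insertion=False)
        calls = rd.call_polymorphic_insertions(genomes, annots, "172TR")
        assert not calls["called"].any()

    def test_insertion_shared_by_two_not_called(self):
        genomes, annots = self._trio()
        # give C the same extra insertion as A (same seed, same prior state)
        genomes["C"] = simgen.plant_repeats(
            genomes["C"],
            simgen.RepeatFamilySpec("172TR", "ITR", consensus_length=516,
                                    mode="tandem", monomer_length=172),
            1, array_length_range=(1_500, 1_500), seed=32,
        )
        annots["C"] = repeatscape.annotations_from_truth(genomes["C"].truth)
        calls = rd.call_polymorphic_insertions(genomes, annots, "172TR")
        assert not calls["called"].any()
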