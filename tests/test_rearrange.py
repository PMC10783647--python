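"""Orientation blocks, breakpoint intervals, and fixed/polymorphic status."""

import itertools

import pytest

from viriscape import alignio, rearrange, simgen
from viriscape.alignio import AlignmentSegment


def seg(rs, re, qs, qe, strand="+", rc="chr1", qc="chr1"):
    return AlignmentSegment(rc, rs, re, qc, qs, qe, strand, 99.0)


def brute_force_runs(entries, max_gap):
    """Oracle: maximal runs of same-strand, query-monotone, gap-bounded
    segments, found by exhaustively testing every split refinement."""
    def run_ok(run):
        for (r1, q1, s1), (r2, q2, s2) in zip(run, run[1:]):
            if s1 != s2 or r2[0] - r1[1] > max_gap:
                return False
            if s1 == "+" and q2[0] < q1[1]:
                return False
            if s1 == "-" and q2[1] > q1[0]:
                return False
        return True

    n = len(entries)
    best = None
    for cuts in itertools.product([0, 1], repeat=n - 1):
        runs, cur = [], [entries[0]]
        for i, cut in enumerate(cuts):
            if cut:
                runs.append(cur)
                cur = []
            cur.append(entries[i + 1])
        runs.append(cur)
        if all(run_ok(r) for r in runs):
            if best is None or len(runs) < len(best):
                best = runs
    return best


class TestBuildBlocks:
    def test_colinear_plus_segments_single_block(self):
        segs = [seg(0, 100, 0, 100), seg(200, 300, 200, 300), seg(400, 500, 400, 500)]
        blocks = rearrange.build_blocks(segs, max_intra_gap=1_000)
        assert len(blocks) == 1
        assert blocks[0].strand == "+" and blocks[0].n_segments == 3

    def test_strand_pattern_splits_into_three_blocks(self):
        segs = [
            seg(0, 100, 0, 100, "+"),
            seg(150, 250, 150, 250, "+"),
            seg(300, 400, 900, 1_000, "-"),
            seg(450, 550, 750, 850, "-"),
            seg(600, 700, 1_100, 1_200, "+"),
        ]
        blocks = rearrange.build_blocks(segs, max_intra_gap=1_000)
        assert [b.strand for b in blocks] == ["+", "-", "+"]

    def test_monotonicity_break_splits_translocation(self):
        # same strand throughout, but query jumps backwards mid-run
        entries = [
            ((0, 100), (0, 100), "+"),
            ((150, 250), (150, 250), "+"),
            ((300, 400), (2_000, 2_100), "+"),
            ((450, 550), (2_150, 2_250), "+"),
            ((600, 700), (400, 500), "+"),
            ((750, 850), (550, 650), "+"),
        ]
        segs = [seg(r[0], r[1], q[0], q[1], s) for r, q, s in entries]
        blocks = rearrange.build_blocks(segs, max_intra_gap=1_000)
        oracle = brute_force_runs(entries, 1_000)
        assert [b.n_segments for b in blocks] == [len(r) for r in oracle]

    def test_mixed_chromosomes_rejected(self):
        segs = [seg(0, 100, 0, 100, rc="chr1"), seg(0, 100, 0, 100, rc="chr2")]
        with pytest.raises(ValueError, match="multiple chromosomes"):
            rearrange.build_blocks(segs)


class TestCallBreakpoints:
    def test_gap_between_opposite_blocks(self):
        segs = [seg(0, 9_980, 0, 9_980, "+"), seg(10_020, 20_000, 20_000, 30_000, "-")]
        blocks = rearrange.build_blocks(segs)
        (bp,) = rearrange.call_breakpoints(blocks)
        assert (bp.start, bp.end, bp.resolution) == (9_980, 10_020, 40)

    def test_single_block_no_breakpoints(self):
        blocks = rearrange.build_blocks([seg(0, 100, 0, 100)])
        assert rearrange.call_breakpoints(blocks) == []

    def test_abutting_blocks_zero_width(self):
        segs = [seg(0, 10_000, 0, 10_000, "+"), seg(10_000, 20_000, 20_000, 30_000, "-")]
        bps = rearrange.call_breakpoints(rearrange.build_blocks(segs))
        assert bps[0].resolution == 0
        assert bps[0].contains(10_000)

    def test_strand_flip_count_equals_breakpoint_count(self):
        strands = ["+", "-", "-", "+", "-", "+", "+"]
        segs = []
        q = 0
        for i, st in enumerate(strands):
            rs = i * 1_000
            segs.append(seg(rs, rs + 500, 50_000 + q if st == "+" else 100_000 - q,
                            50_000 + q + 500 if st == "+" else 100_500 - q, st))
            q += 600
        blocks = rearrange.build_blocks(segs, max_intra_gap=10_000)
        flips = sum(1 for a, b in zip(blocks, blocks[1:]) if a.strand != b.strand)
        assert len(rearrange.call_breakpoints(blocks)) == flips


class TestEndToEndOnPlantedInversions:
    def test_zero_divergence_breakpoints_tight_and_complete(self):
        anc = simgen.make_random_genome({"c": 300_000}, seed=50)
        invs = [("c", 60_000, 110_000), ("c", 180_000, 240_000)]
        der = simgen.apply_inversions(anc, invs)
        segs = alignio.filter_segments(alignio.anchor_align(anc, der, anchor_k=20))
        blocks = rearrange.build_blocks(segs)
        bps = rearrange.call_breakpoints(blocks, junction_guard=20)
        assert len(bps) == 2 * len(invs)
        # with zero divergence each interval is the guard plus at most one
        # anchor length of genuine junction ambiguity
        assert all(bp.resolution <= 3 * 20 for bp in bps)
        for _, pos in der.truth.breakpoints():
            assert any(bp.contains(pos) for bp in bps)

    def test_reverse_complemented_query_same_reference_breakpoints(self):
        from viriscape._seqcodes import revcomp

        anc = simgen.make_random_genome({"c": 200_000}, seed=51)
        der = simgen.apply_inversions(anc, [("c", 50_000, 120_000)])
        der_rc = simgen.Genome({"c": revcomp(der["c"])})

        def bkpt_positions(query):
            segs = alignio.filter_segments(alignio.anchor_align(anc, query, anchor_k=20))
            blocks = rearrange.build_blocks(segs)
            return sorted((b.start, b.end) for b in rearrange.call_breakpoints(blocks))

        assert bkpt_positions(der) == bkpt_positions(der_rc)


class TestClassifySharing:
    def _inv(self, left, right, chrom="chr1"):
        return (chrom, left, right)

    def test_identical_sets_all_fixed(self):
        invs = [self._inv(10_000, 50_000), self._inv(80_000, 90_000)]
        res = rearrange.classify_sharing({"s1": invs, "s2": invs, "s3": invs})
        assert (res["status"] == "fixed").all()
        assert len(res) == 2

    def test_private_inversion_polymorphic(self):
        shared = [self._inv(10_000, 50_000)]
        private = shared + [self._inv(70_000, 95_000)]
        res = rearrange.classify_sharing({"s1": private, "s2": shared, "s3": shared})
        status = dict(zip(res["left"], res["status"]))
        assert status[10_000] == "fixed"
        assert status[70_000] == "polymorphic"

    def test_boundaries_beyond_tolerance_are_distinct(self):
        a = [self._inv(10_000, 50_000)]
        b = [self._inv(10_000 + 1_001, 50_000)]
        res = rearrange.classify_sharing({"s1": a, "s2": b}, match_tol=1_000)
        assert len(res) == 2
        assert (res["status"] == "polymorphic").all()

    def test_different_references_rejected(self):
        invs = [self._inv(1_000, 2_000)]
        with pytest.raises(ValueError, match="different references"):
            rearrange.classify_sharing(
                {"s1": invs, "s2": invs},
                references={"s1": "genomeA", "s2": "genomeB"},
            )
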