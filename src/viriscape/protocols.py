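"""Canonical simulation protocols for validating the pipeline.

Each function builds one complete study-condition experiment — genome
composition, read depths, divergences and planting densities are fixed
here, in one place — and runs the corresponding analysis end to end,
returning both the results and the planted truth. The test-suite and the
reproduction script both call these, so the conditions cannot drift apart.

Problem sizes (a 5-Mb thirty-contig assembly for the sex experiment, a
2-Mb chromosome for the breakpoint experiment, sub-Mb replicates for the
calibration and trio studies) are chosen as the smallest scales at which
the statistical expectations under test are comfortably resolvable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import alignio, bkpt_enrich, rearrange, repeat_dynamics, repeatscape, sexlink, simgen


def _spawn(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2^31."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# sexed coverage / Y-classification experiment


def sex_genome(seed: int) -> simgen.Genome:
    """A 5-Mb assembly: 20 autosomal 175-kb, 6 X 150-kb and 4 Y 150-kb contigs."""
    lengths = {f"A{i:02d}": 175_000 for i in range(20)}
    lengths |= {f"X{i}": 150_000 for i in range(6)}
    lengths |= {f"Y{i}": 150_000 for i in range(4)}
    classes = {c: c[0] for c in lengths}
    return simgen.make_random_genome(lengths, seed=seed, contig_class=classes)


def run_sex_experiment(
    seed: int,
    depth: float = 30.0,
    read_length: int = 150,
    with_kmers: bool = True,
) -> dict:
    """Simulate male/female read sets and classify every contig.

    Coverage is exact by construction (read provenance is known); the
    k-mer stage (skippable for coverage-only questions) scans the female
    set at k=15.
    """
    s_g, s_r = _spawn(seed, 2)
    genome = sex_genome(s_g)
    male, female = simgen.simulate_sex_reads(
        genome, depth, read_length=read_length, seed=s_r
    )
    cov = sexlink.coverage_from_mapping_table(
        female.coverage_table(genome.lengths()),
        male.coverage_table(genome.lengths()),
    )
    cov["true_class"] = cov["contig"].map(genome.truth.contig_class)
    out = {"genome": genome, "male": male, "female": female, "coverage": cov}
    if with_kmers:
        fk = sexlink.count_read_kmers(female, k=15)
        stats = sexlink.contig_kmer_stats(genome, fk, k=15)
        profiles = sexlink.classify_contigs(sexlink.build_profiles(stats, cov))
        out["profiles"] = profiles
    return out


def class_ratio_means(coverage: pd.DataFrame) -> dict[str, float]:
    return coverage.groupby("true_class")["ratio_fm"].mean().to_dict()


# ---------------------------------------------------------------------------
# inversion-breakpoint experiment


def run_breakpoint_experiment(
    seed: int,
    length: int = 2_000_000,
    n_inversions: int = 5,
    size_range: tuple[int, int] = (50_000, 300_000),
    divergence: float = 0.01,
    anchor_k: int = 20,
) -> dict:
    """Ancestor/derived pair with planted inversions, aligned and called.

    The derived genome is the ancestor mutated at ``divergence`` with
    ``n_inversions`` non-overlapping inversions applied (at least 10 kb
    apart so inter-inversion blocks survive the span filter). Segments are
    filtered at the standard 100 bp / 90% / 1 kb thresholds and
    breakpoints called with a junction guard of one anchor length.
    """
    s_g, s_m, s_p = _spawn(seed, 3)
    rng = np.random.default_rng(s_p)
    sizes = rng.integers(size_range[0], size_range[1] + 1, size=n_inversions)
    min_gap = 10_000
    free = length - int(sizes.sum()) - (n_inversions + 1) * min_gap
    if free < 0:
        raise ValueError("inversions do not fit the chromosome")
    cuts = np.sort(rng.random(n_inversions + 1))
    gaps = min_gap + np.diff(np.concatenate(([0.0], cuts))) / cuts[-1] * free
    spec, pos = [], 0
    for size, gap in zip(sizes, gaps):
        pos += int(gap)
        spec.append(("chr1", pos, pos + int(size)))
        pos += int(size)

    anc = simgen.make_random_genome({"chr1": length}, seed=s_g)
    der = simgen.Genome({"chr1": simgen.mutate_sequence(anc["chr1"], divergence, seed=s_m)})
    der = simgen.apply_inversions(der, spec)

    segments = alignio.filter_segments(alignio.anchor_align(anc, der, anchor_k=anchor_k))
    blocks = rearrange.build_blocks(segments)
    breakpoints = rearrange.call_breakpoints(blocks, junction_guard=anchor_k)
    truth = der.truth.breakpoints()
    contained = [any(b.contains(p) for b in breakpoints) for _, p in truth]
    widths = [b.resolution for b in breakpoints]
    return {
        "ancestor": anc,
        "derived": der,
        "segments": segments,
        "breakpoints": breakpoints,
        "truth_breakpoints": truth,
        "all_contained": all(contained),
        "max_width": max(widths) if widths else float("nan"),
    }


# ---------------------------------------------------------------------------
# permutation-test constructions


def calibration_replicate(seed: int, n_perm: int = 500) -> float:
    """One null replicate: uniformly planted target, random breakpoints.

    Breakpoint regions are drawn exactly as the permutation null draws
    them, so the resulting p-value is uniform up to the discreteness of
    the statistic; the replicate returns that p-value.
    """
    s_g, s_f, s_b, s_p = _spawn(seed, 4)
    genome = simgen.make_random_genome({"chr1": 400_000}, seed=s_g)
    # variable-length copies keep the overlap statistic nearly continuous
    # (fixed-length copies would tie the extended statistic at multiples of
    # the copy length and make the p-value conservative)
    fam = simgen.RepeatFamilySpec(
        "target", "Helitron/DINE-TR", consensus_length=300,
        mode="tandem", monomer_length=29,
    )
    genome = simgen.plant_repeats(
        genome, fam, 200, array_length_range=(100, 500), seed=s_f
    )
    annots = repeatscape.annotations_from_truth(genome.truth)
    rng = np.random.default_rng(s_b)
    L = genome.total_length()
    width = 500
    bkpts = []
    for _ in range(10):
        s = int(rng.integers(0, L - width + 1))
        bkpts.append(("chr1", s, s + width))
    res = bkpt_enrich.permutation_test(
        bkpts, annots, "target", genome.lengths(), n_perm=n_perm, seed=s_p
    )
    return res.p_value


def flank_replicate(seed: int, n_perm: int = 500) -> tuple[float, int]:
    """One enrichment replicate: target planted only at inversion junctions."""
    s_g, s_i, s_p = _spawn(seed, 3)
    genome = simgen.make_random_genome({"chr1": 300_000}, seed=s_g)
    fam = simgen.RepeatFamilySpec("target", "DNA-TIR", consensus_length=200)
    genome = simgen.apply_inversions(
        genome,
        [("chr1", 60_000, 130_000), ("chr1", 190_000, 250_000)],
        flank_element=fam,
        seed=s_i,
    )
    annots = repeatscape.annotations_from_truth(genome.truth)
    bkpts = [(c, p - 1, p + 1) for c, p in genome.truth.breakpoints()]
    res = bkpt_enrich.permutation_test(
        bkpts, annots, "target", genome.lengths(), n_perm=n_perm, seed=s_p
    )
    return res.p_value, res.observed_bp


# ---------------------------------------------------------------------------
# repeat-dynamics trio


def build_trio(seed: int) -> dict:
    """Three genomes from one ancestor, with known repeat dynamics.

    All three share two interspersed families and two tandem (ITR) arrays
    planted in the common ancestor. Genome A additionally carries: a
    species-unique family meeting the novelty criteria (12 x 500 bp = 6 kb
    at 1-6% divergence), a low-abundance decoy singleton (3 x 300 bp,
    below the 5-kb bar), and one private 1.5-kb ITR tandem array at an
    isolated locus (the polymorphic-insertion truth).
    """
    seeds = _spawn(seed, 10)
    base = simgen.make_random_genome({"chr1": 120_000, "chr2": 80_000}, seed=seeds[0])
    shared_ltr = simgen.RepeatFamilySpec("shared_LTR", "LTR", consensus_length=400)
    shared_line = simgen.RepeatFamilySpec("shared_LINE", "LINE", consensus_length=300)
    itr = simgen.RepeatFamilySpec(
        "172TR", "ITR", consensus_length=516, mode="tandem", monomer_length=172
    )
    uniq = simgen.RepeatFamilySpec("unique_fam", "Unknown", consensus_length=500)
    decoy = simgen.RepeatFamilySpec("decoy_fam", "Unknown", consensus_length=300)
    for spec, s in zip((shared_ltr, shared_line, itr, uniq, decoy), seeds[1:6]):
        spec.realize(seed=s)

    base = simgen.plant_repeats(base, shared_ltr, 6, divergence_range=(0.02, 0.08), seed=seeds[6])
    base = simgen.plant_repeats(base, shared_line, 5, divergence_range=(0.02, 0.08), seed=seeds[7])
    base = simgen.plant_repeats(base, itr, 2, array_length_range=(800, 2_000), seed=seeds[8])

    genomes = {"A": base.copy(), "B": base.copy(), "C": base.copy()}
    g = simgen.plant_repeats(genomes["A"], uniq, 12, divergence_range=(0.01, 0.06), seed=seeds[9])
    g = simgen.plant_repeats(g, decoy, 3, divergence_range=(0.01, 0.05), seed=seeds[9] + 1)

    # the private ITR array must be an *eligible* locus: isolated from other
    # annotations and with full flanks; replant deterministically until so
    for attempt in range(60):
        g_try = simgen.plant_repeats(
            g, itr, 1, array_length_range=(1_500, 1_500), seed=seeds[9] + 2 + attempt
        )
        locus = g_try.truth.planted_repeats[-1]
        others = [
            r for r in g_try.truth.planted_repeats
            if r is not locus and r.chrom == locus.chrom
        ]
        isolated = all(
            r.end <= locus.start - 1_100 or r.start >= locus.end + 1_100 for r in others
        )
        contig_len = len(g_try[locus.chrom])
        has_flanks = locus.start >= 150 and locus.end + 150 <= contig_len
        if isolated and has_flanks:
            genomes["A"] = g_try
            break
    else:
        raise RuntimeError("could not place an isolated private array")

    annotations = {
        n: repeatscape.annotations_from_truth(gn.truth) for n, gn in genomes.items()
    }
    libraries = {
        "A": [
            repeat_dynamics.RepeatFamily("shared_LTR", shared_ltr.consensus, "A", "LTR"),
            repeat_dynamics.RepeatFamily("shared_LINE", shared_line.consensus, "A", "LINE"),
            repeat_dynamics.RepeatFamily("unique_fam", uniq.consensus, "A", "Unknown"),
            repeat_dynamics.RepeatFamily("decoy_fam", decoy.consensus, "A", "Unknown"),
        ],
        "B": [
            repeat_dynamics.RepeatFamily("shared_LTR", shared_ltr.consensus, "B", "LTR"),
            repeat_dynamics.RepeatFamily("shared_LINE", shared_line.consensus, "B", "LINE"),
        ],
        "C": [
            repeat_dynamics.RepeatFamily("shared_LTR", shared_ltr.consensus, "C", "LTR"),
            repeat_dynamics.RepeatFamily("shared_LINE", shared_line.consensus, "C", "LINE"),
        ],
    }
    private = genomes["A"].truth.planted_repeats[-1]
    return {
        "genomes": genomes,
        "annotations": annotations,
        "libraries": libraries,
        "true_novel": {"unique_fam"},
        "false_singletons": {"decoy_fam"},
        "private_insertion": ("A", private.chrom, private.start, private.end),
    }


def run_trio(seed: int) -> dict:
    """Novelty report and polymorphic-insertion calls for one trio."""
    trio = build_trio(seed)
    report = repeat_dynamics.novel_family_report(
        trio["libraries"], trio["genomes"], trio["annotations"]
    )
    calls = repeat_dynamics.call_polymorphic_insertions(
        trio["genomes"], trio["annotations"], "172TR"
    )
    return {**trio, "novel_report": report, "insertion_calls": calls}
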