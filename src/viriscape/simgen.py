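"""Synthetic genomes, repeat plantings, sex-specific reads and genotype panels.

This module fabricates the inputs the rest of the package analyses, with an
exact truth ledger for every planted feature, so that breakpoint calling,
Y-contig classification, repeat landscapes and diversity estimates can be
checked against known answers. The simulator mirrors the statistical
structure those analyses assume:

* genomes are iid base sequences at a chosen GC content (no higher-order
  composition structure);
* repeat copies diverge from their family consensus by substitutions only,
  at a per-site rate drawn from a caller-specified range, so the divergence
  landscape of planted copies is analytically binomial;
* inversions reverse-complement an interval in place, optionally with one
  mobile-element copy planted adjacent to each breakpoint (the construction
  used for enrichment tests);
* male and female read sets differ only in per-contig dose (female carries
  two X doses and no Y), with uniform single-end reads;
* genotype panels are haploid: each sample's allele at each site is an iid
  Bernoulli draw with success probability p chosen so that expected
  per-site heterozygosity 2p(1-p) equals the requested diversity.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seqcodes as sc

__all__ = [
    "RepeatFamilySpec",
    "PlantedRepeat",
    "SimTruth",
    "Genome",
    "ReadSet",
    "make_random_genome",
    "mutate_sequence",
    "plant_repeats",
    "apply_inversions",
    "simulate_reads",
    "simulate_sex_reads",
    "simulate_genotype_panel",
    "read_fasta",
    "write_fasta",
    "write_sites_tsv",
    "read_sites_tsv",
]

#: Per-contig-class sampling weight ("dose") by sex. A male fly carries one
#: dose of every chromosome class; a female carries two X doses and no Y.
SEX_DOSES = {
    "male": {"A": 1.0, "X": 1.0, "Y": 1.0},
    "female": {"A": 1.0, "X": 2.0, "Y": 0.0},
}

_SUBCLASSES = ("LTR", "LINE", "DNA-TIR", "Helitron/DINE-TR", "ITR", "Unknown")


@dataclass
class RepeatFamilySpec:
    """A repeat family to plant: interspersed TE-like or tandem-array (ITR-like)."""

    name: str
    subclass: str = "Unknown"
    consensus_length: int = 500
    mode: str = "interspersed"
    monomer_length: int | None = None
    consensus: str | None = None

    def __post_init__(self):
        if self.subclass not in _SUBCLASSES:
            raise ValueError(f"unknown subclass {self.subclass!r}")
        if self.consensus_length < 50:
            raise ValueError("consensus_length must be >= 50")
        if self.mode not in ("interspersed", "tandem"):
            raise ValueError("mode must be 'interspersed' or 'tandem'")
        if self.mode == "tandem":
            if self.monomer_length is None or self.monomer_length < 7:
                raise ValueError("tandem families need monomer_length >= 7")

    def realize(self, seed: int | None = None) -> str:
        """Generate (once) and return the family consensus sequence.

        Tandem families realize a monomer and tile it to ``consensus_length``
        so the consensus used for homology search is a representative array.
        """
        if self.consensus is None:
            rng = np.random.default_rng(seed)
            unit = self.monomer_length if self.mode == "tandem" else self.consensus_length
            codes = rng.integers(0, 4, size=unit).astype(np.uint8)
            monomer = sc.decode(codes)
            if self.mode == "tandem":
                reps = -(-self.consensus_length // len(monomer))
                self.consensus = (monomer * reps)[: self.consensus_length]
                self._monomer = monomer
            else:
                self.consensus = monomer
        return self.consensus

    @property
    def monomer(self) -> str:
        if self.mode != "tandem":
            raise ValueError("monomer only defined for tandem families")
        self.realize()
        return self._monomer


@dataclass
class PlantedRepeat:
    chrom: str
    start: int
    end: int
    family: str
    subclass: str
    divergence: float
    mode: str


@dataclass
class SimTruth:
    """Exact ledger of every planted feature, in current genome coordinates."""

    planted_inversions: list = field(default_factory=list)  # (chrom, start, end)
    planted_repeats: list = field(default_factory=list)  # PlantedRepeat
    contig_class: dict = field(default_factory=dict)  # contig -> {A, X, Y}

    def copy(self) -> "SimTruth":
        return SimTruth(
            planted_inversions=list(self.planted_inversions),
            planted_repeats=[dataclasses.replace(r) for r in self.planted_repeats],
            contig_class=dict(self.contig_class),
        )

    def breakpoints(self) -> list[tuple[str, int]]:
        """Planted inversion boundaries as (chrom, position) points."""
        out = []
        for chrom, s, e in self.planted_inversions:
            out.append((chrom, s))
            out.append((chrom, e))
        return out

    def repeats_on(self, chrom: str) -> list[PlantedRepeat]:
        return [r for r in self.planted_repeats if r.chrom == chrom]

    def to_json(self, path) -> None:
        obj = {
            "planted_inversions": [list(t) for t in self.planted_inversions],
            "planted_repeats": [dataclasses.asdict(r) for r in self.planted_repeats],
            "contig_class": self.contig_class,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


class Genome:
    """A set of contig sequences plus the truth ledger of planted features."""

    def __init__(self, seqs: dict[str, str], truth: SimTruth | None = None):
        self.seqs = dict(seqs)
        self.truth = truth if truth is not None else SimTruth()

    def __getitem__(self, contig: str) -> str:
        return self.seqs[contig]

    def __contains__(self, contig) -> bool:
        return contig in self.seqs

    def __iter__(self):
        return iter(self.seqs)

    def __len__(self) -> int:
        return len(self.seqs)

    def items(self):
        return self.seqs.items()

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self.seqs.values())

    def copy(self) -> "Genome":
        return Genome(dict(self.seqs), self.truth.copy())


# ---------------------------------------------------------------------------
# genome construction


def make_random_genome(
    contig_lengths: dict[str, int],
    gc: float = 0.45,
    seed: int | None = None,
    contig_class: dict[str, str] | None = None,
) -> Genome:
    """Random iid genome with the requested GC fraction.

    ``contig_class`` optionally assigns each contig to {A, X, Y}; unassigned
    contigs default to autosomal.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be within [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    seqs = {}
    for name, length in contig_lengths.items():
        if length <= 0:
            raise ValueError(f"contig {name!r}: length must be positive, got {length}")
        if length < 1000:
            raise ValueError(f"contig {name!r}: minimum simulated contig length is 1 kb")
        codes = rng.choice(4, size=length, p=p).astype(np.uint8)
        seqs[name] = sc.decode(codes)
    truth = SimTruth(contig_class={c: "A" for c in seqs})
    if contig_class:
        truth.contig_class.update(contig_class)
    return Genome(seqs, truth)


def mutate_sequence(seq: str, divergence: float, seed: int | None = None) -> str:
    """Substitute each site with probability ``divergence`` (no indels).

    A substituted site is drawn uniformly from the three alternative bases,
    so the expected Hamming mismatch fraction equals ``divergence`` exactly.
    """
    if not 0.0 <= divergence <= 0.4:
        raise ValueError("divergence must be within [0, 0.4]")
    if divergence == 0.0 or not seq:
        return seq
    rng = np.random.default_rng(seed)
    codes = sc.encode(seq)
    hit = (rng.random(codes.size) < divergence) & (codes <= 3)
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum())).astype(np.uint8)
        codes = codes.copy()
        codes[hit] = (codes[hit] + shift) % 4
    return sc.decode(codes)


# ---------------------------------------------------------------------------
# insertion machinery (shared by plant_repeats and breakpoint-flank planting)


def _shift_truth_for_insert(truth: SimTruth, chrom: str, pos: int, length: int) -> None:
    """Shift ledger coordinates on ``chrom`` for an insertion of ``length`` at ``pos``."""
    inv = []
    for c, s, e in truth.planted_inversions:
        if c == chrom:
            if pos <= s:
                s, e = s + length, e + length
            elif pos < e:
                e = e + length
        inv.append((c, s, e))
    truth.planted_inversions = inv
    for r in truth.planted_repeats:
        if r.chrom == chrom:
            if pos <= r.start:
                r.start += length
                r.end += length
            elif pos < r.end:
                r.end += length


def _apply_insertions(genome: Genome, insertions) -> Genome:
    """Splice insertions into a genome copy, keeping all truth coordinates exact.

    ``insertions`` is a list of ``(chrom, pos, seq, meta)`` in *current*
    coordinates; ``meta`` is a PlantedRepeat whose start/end are filled here.
    """
    out = genome.copy()
    by_chrom: dict[str, list] = {}
    for ins in insertions:
        by_chrom.setdefault(ins[0], []).append(ins)
    for chrom, items in by_chrom.items():
        items.sort(key=lambda t: t[1])
        seq = out.seqs[chrom]
        parts, prev, offset = [], 0, 0
        for _, pos, ins_seq, meta in items:
            parts.append(seq[prev:pos])
            parts.append(ins_seq)
            # shift pre-existing features first, then record the new copy so
            # the fresh entry is not displaced by its own insertion
            _shift_truth_for_insert(out.truth, chrom, pos + offset, len(ins_seq))
            if meta is not None:
                meta.start = pos + offset
                meta.end = pos + offset + len(ins_seq)
                out.truth.planted_repeats.append(meta)
            offset += len(ins_seq)
            prev = pos
        parts.append(seq[prev:])
        out.seqs[chrom] = "".join(parts)
    return out


def _sample_insertion_positions(
    rng: np.random.Generator,
    genome: Genome,
    n: int,
    contigs: list[str] | None,
) -> list[tuple[str, int]]:
    """Uniform insertion points excluding the interior of planted features."""
    names = list(contigs) if contigs else list(genome.seqs)
    lengths = np.array([len(genome.seqs[c]) for c in names], dtype=float)
    if lengths.sum() <= 0:
        raise ValueError("genome too small to host requested copies")
    weights = lengths / lengths.sum()
    blocked = {
        c: [(r.start, r.end) for r in genome.truth.repeats_on(c)] for c in names
    }
    chosen: list[tuple[str, int]] = []
    taken: dict[str, set[int]] = {c: set() for c in names}
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 1000 * max(n, 1):
            raise ValueError("genome too small to host requested copies")
        ci = rng.choice(len(names), p=weights)
        c = names[ci]
        pos = int(rng.integers(0, len(genome.seqs[c]) + 1))
        if pos in taken[c]:
            continue
        if any(s < pos < e for s, e in blocked[c]):
            continue
        taken[c].add(pos)
        chosen.append((c, pos))
    return chosen


def plant_repeats(
    genome: Genome,
    family: RepeatFamilySpec,
    n_copies: int,
    array_length_range: tuple[int, int] | None = None,
    divergence_range: tuple[float, float] = (0.0, 0.0),
    seed: int | None = None,
    contigs: list[str] | None = None,
) -> Genome:
    """Insert ``n_copies`` of a repeat family at uniform positions.

    Interspersed mode inserts one mutated consensus copy per site; tandem
    mode inserts a head-to-tail monomer array whose length is drawn
    uniformly from ``array_length_range``. Returns a new genome whose truth
    ledger records the exact coordinates of every copy (and of every
    pre-existing feature, shifted consistently).
    """
    lo, hi = divergence_range
    if not (0.0 <= lo <= hi <= 0.4):
        raise ValueError("divergence_range must satisfy 0 <= lo <= hi <= 0.4")
    if family.mode == "tandem" and array_length_range is None:
        raise ValueError("tandem planting requires array_length_range")
    if n_copies == 0:
        return genome.copy()
    rng = np.random.default_rng(seed)
    family.realize(seed=rng.integers(0, 2**31 - 1))
    positions = _sample_insertion_positions(rng, genome, n_copies, contigs)
    insertions = []
    for chrom, pos in positions:
        div = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        if family.mode == "tandem":
            alen = int(rng.integers(array_length_range[0], array_length_range[1] + 1))
            monomer = family.monomer
            reps = -(-alen // len(monomer))
            ins = (monomer * reps)[:alen]
        else:
            ins = family.consensus
        ins = mutate_sequence(ins, div, seed=int(rng.integers(0, 2**31 - 1)))
        meta = PlantedRepeat(chrom, -1, -1, family.name, family.subclass, div, family.mode)
        insertions.append((chrom, pos, ins, meta))
    return _apply_insertions(genome, insertions)


def apply_inversions(
    genome: Genome,
    spec: list[tuple[str, int, int]],
    flank_element: RepeatFamilySpec | None = None,
    seed: int | None = None,
    flank_divergence: float = 0.0,
) -> Genome:
    """Reverse-complement each listed interval in place.

    Intervals are 0-based half-open and must be non-overlapping and within
    bounds. If ``flank_element`` is given, one mutated copy of it is planted
    immediately at each breakpoint (two copies per inversion), emulating
    mobile elements residing at inversion boundaries.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in spec:
        if chrom not in genome.seqs:
            raise ValueError(f"unknown contig {chrom!r}")
        L = len(genome.seqs[chrom])
        if not (0 <= s < e <= L):
            raise ValueError(f"inversion ({chrom}, {s}, {e}) out of bounds (contig {L} bp)")
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping inversions on {chrom}: [{s1},{e1}) and [{s2},{e2})")

    out = genome.copy()
    for chrom, ivs in by_chrom.items():
        seq = out.seqs[chrom]
        for s, e in ivs:
            seq = seq[:s] + sc.revcomp(seq[s:e]) + seq[e:]
            # mirror coordinates of planted repeats fully inside the interval
            for r in out.truth.planted_repeats:
                if r.chrom == chrom and s <= r.start and r.end <= e:
                    r.start, r.end = s + e - r.end, s + e - r.start
            out.truth.planted_inversions.append((chrom, s, e))
        out.seqs[chrom] = seq

    if flank_element is not None:
        rng = np.random.default_rng(seed)
        flank_element.realize(seed=rng.integers(0, 2**31 - 1))
        insertions = []
        for chrom, ivs in by_chrom.items():
            for s, e in ivs:
                for pos in (s, e):
                    ins = mutate_sequence(
                        flank_element.consensus,
                        flank_divergence,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                    meta = PlantedRepeat(
                        chrom, -1, -1, flank_element.name,
                        flank_element.subclass, flank_divergence, flank_element.mode,
                    )
                    insertions.append((chrom, pos, ins, meta))
        out = _apply_insertions(out, insertions)
    return out


# ---------------------------------------------------------------------------
# reads


class ReadSet:
    """Uniform single-end reads held as per-contig numpy code matrices.

    Keeping reads encoded (rather than as strings) lets k-mer counting and
    FASTQ export share one representation; read provenance (source contig
    and start) is retained so per-contig coverage is known by construction.
    """

    def __init__(self, read_length: int, label: str = "reads"):
        self.read_length = read_length
        self.label = label
        self.chunks: list[tuple[str, np.ndarray, np.ndarray]] = []

    def add(self, contig: str, starts: np.ndarray, codes: np.ndarray) -> None:
        self.chunks.append((contig, starts, codes))

    @property
    def n_reads(self) -> int:
        return sum(c[1].size for c in self.chunks)

    @property
    def total_bases(self) -> int:
        return self.n_reads * self.read_length

    def coverage_table(self, contig_lengths: dict[str, int]) -> pd.DataFrame:
        """Exact per-contig mean depth (read bases / contig length)."""
        bases = {c: 0 for c in contig_lengths}
        for contig, starts, _ in self.chunks:
            bases[contig] += starts.size * self.read_length
        rows = [
            {"contig": c, "mean_depth": bases[c] / contig_lengths[c]}
            for c in contig_lengths
        ]
        return pd.DataFrame(rows)

    def iter_reads(self):
        qual = "I" * self.read_length
        for contig, starts, codes in self.chunks:
            for i in range(starts.size):
                name = f"{self.label}|{contig}|{int(starts[i])}|{i}"
                yield name, sc.decode(codes[i]), qual

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq, qual in self.iter_reads():
                fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def simulate_reads(
    genome: Genome,
    depth: float,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int | None = None,
    doses: dict[str, float] | None = None,
    label: str = "reads",
) -> ReadSet:
    """Uniform error-prone single-end reads at ``depth``-fold coverage.

    ``doses`` maps chromosome class (or contig name) to a sampling-weight
    multiplier; expected per-contig depth is ``depth * dose``. Contigs
    shorter than the read length are skipped with a warning.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    reads = ReadSet(read_length, label=label)
    classes = genome.truth.contig_class
    for contig, seq in genome.items():
        dose = 1.0
        if doses is not None:
            if contig in doses:
                dose = doses[contig]
            else:
                dose = doses.get(classes.get(contig, "A"), 1.0)
        if dose <= 0:
            continue
        L = len(seq)
        if read_length > L:
            warnings.warn(f"contig {contig!r} shorter than read length; skipped")
            continue
        n = int(round(depth * dose * L / read_length))
        if n == 0:
            continue
        starts = rng.integers(0, L - read_length + 1, size=n)
        contig_codes = sc.encode(seq)
        mat = contig_codes[starts[:, None] + np.arange(read_length)]
        if error_rate > 0:
            hit = rng.random(mat.shape) < error_rate
            shift = rng.integers(1, 4, size=int(hit.sum())).astype(np.uint8)
            mat[hit] = (mat[hit] + shift) % 4
        reads.add(contig, starts, mat)
    return reads


def simulate_sex_reads(
    genome: Genome,
    depth: float,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int | None = None,
) -> tuple[ReadSet, ReadSet]:
    """Male and female read sets under the standard dose model.

    Male: one dose of A, X and Y contigs. Female: one A dose, two X doses,
    no Y (dose realized by sampling weight, not by sequence duplication).
    """
    ss = np.random.SeedSequence(seed)
    s_m, s_f = ss.spawn(2)
    male = simulate_reads(
        genome, depth, read_length, error_rate,
        seed=int(s_m.generate_state(1)[0] % (2**31 - 1)),
        doses=SEX_DOSES["male"], label="male",
    )
    female = simulate_reads(
        genome, depth, read_length, error_rate,
        seed=int(s_f.generate_state(1)[0] % (2**31 - 1)),
        doses=SEX_DOSES["female"], label="female",
    )
    return male, female


# ---------------------------------------------------------------------------
# genotype panels


def simulate_genotype_panel(
    n_samples: int | dict[str, int],
    n_sites: int,
    pi_target: float,
    missing_rate: float = 0.0,
    chrom: str = "chr1",
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Haploid genotype panel with controlled expected diversity.

    Each sample's allele at each site is an iid Bernoulli(p) draw with p
    solving 2p(1-p) = ``pi_target``, so expected per-site heterozygosity is
    exactly the target; genotypes then go missing independently at
    ``missing_rate``. Returns a long site table (one row per population per
    site, invariant sites included) and a truth dict with the underlying
    allele-frequency parameter and the full pre-missingness alt counts.
    """
    if isinstance(n_samples, int):
        n_samples = {"pop1": n_samples}
    for pop, n in n_samples.items():
        if n < 2:
            raise ValueError(f"population {pop!r}: need at least 2 haploid samples")
    if not 0.0 <= pi_target <= 0.5:
        raise ValueError("pi_target must be in [0, 0.5]")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1); 1.0 leaves no callable site")
    rng = np.random.default_rng(seed)
    p = (1.0 - np.sqrt(1.0 - 2.0 * pi_target)) / 2.0
    pos = np.arange(n_sites)
    frames = []
    truth: dict = {"p_alt": p, "alt_counts": {}}
    for pop, n in n_samples.items():
        alt = rng.random((n, n_sites)) < p
        missing = rng.random((n, n_sites)) < missing_rate
        called = ~missing
        n_called = called.sum(axis=0)
        n_alt = (alt & called).sum(axis=0)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "pop": pop,
                    "allele_count_ref": n_called - n_alt,
                    "allele_count_alt": n_alt,
                    "n_called": n_called,
                }
            )
        )
        truth["alt_counts"][pop] = alt.sum(axis=0)
    return pd.concat(frames, ignore_index=True), truth


# ---------------------------------------------------------------------------
# IO boundaries (1-based conversions happen here)


def write_fasta(genome: Genome | dict[str, str], path, width: int = 80) -> None:
    items = genome.items() if hasattr(genome, "items") else genome
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> Genome:
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return Genome(seqs)


def write_sites_tsv(sites: pd.DataFrame, path) -> None:
    """Site-genotype table with 1-based positions at the file boundary."""
    out = sites.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_sites_tsv(path) -> pd.DataFrame:
    sites = pd.read_csv(path, sep="\t")
    sites["pos"] = sites["pos"] - 1
    return sites


def write_intervals_bed(intervals, path, names=None, scores=None) -> None:
    """BED (0-based half-open) for (chrom, start, end) truth intervals."""
    with open(path, "w") as fh:
        for i, (chrom, s, e) in enumerate(intervals):
            name = names[i] if names else f"iv{i}"
            score = scores[i] if scores else 0
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t{score}\n")
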