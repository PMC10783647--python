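"""Species-unique repeat families and polymorphic tandem-array insertions.

Two cross-genome procedures:

**Novel (species-unique) families.** Repeat libraries from several genomes
are clustered greedily by pairwise identity (longest sequence founds each
cluster). A singleton family — one with no relative at the identity
threshold in any other library — is *novel* only if (a) neither other
genome contains a significant homologous hit (>= 100 bp at >= 80 percent
identity), (b) its own genome carries at least 5 kb of annotated copies,
and (c) those copies average below 10 percent divergence (length-weighted),
which excludes old differentially-degraded families.

**Polymorphic insertions.** For a tandem-array family, loci in one focal
genome that are not flanked by other annotated repeats within 1 kb are
probed by concatenating their 100-bp flanks into a 200-bp junction
sequence, which represents the *intact* (insertion-free) site. An
insertion is called polymorphic when that probe has exactly one continuous
hit at >= 90 percent identity in *both* other genomes — i.e. both carry the
empty site.

Sequence comparison uses banded edit-distance alignment (edlib) with
exact 12-mer seeding to locate candidate regions; gaps count as
differences. Hits below the seeding sensitivity floor (roughly < 80
percent identity) may be missed, which is acceptable given the 80 percent
criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from . import _seqcodes as sc
from .repeatscape import tandem_array_stats

__all__ = [
    "RepeatFamily",
    "GenomeHit",
    "cluster_families",
    "cross_genome_search",
    "is_novel",
    "novel_family_report",
    "eligible_isolated_loci",
    "flank_signature",
    "site_intact",
    "call_polymorphic_insertions",
]

_SEED_K = 12
_DIAG_PAD = 60


@dataclass
class RepeatFamily:
    name: str
    consensus: str
    source_genome: str
    subclass: str = "Unknown"

    def __post_init__(self):
        if len(self.consensus) < 50:
            raise ValueError("family consensus must be >= 50 bp")


@dataclass
class GenomeHit:
    family: str
    chrom: str
    start: int
    end: int
    pct_identity: float

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# pairwise identity and clustering


def _pair_identity(a: str, b: str) -> float:
    """Percent identity of the shorter sequence aligned end-free into the
    longer, best of both orientations; gaps count as differences."""
    if len(a) > len(b):
        a, b = b, a
    best = np.inf
    for query in (a, sc.revcomp(a)):
        res = edlib.align(query, b, mode="HW", task="distance")
        if res["editDistance"] >= 0:
            best = min(best, res["editDistance"])
    if not np.isfinite(best):
        return 0.0
    return 100.0 * (1.0 - best / len(a))


def cluster_families(
    libraries: dict[str, list[RepeatFamily]],
    identity_threshold: float = 0.90,
) -> tuple[list[list[RepeatFamily]], list[RepeatFamily]]:
    """Greedy incremental clustering of repeat libraries.

    Families are sorted by consensus length descending (name as
    tie-break); each joins the first existing cluster whose *founder*
    aligns at ``identity_threshold`` over the shorter sequence, else
    founds a new cluster. Returns all clusters plus the singletons —
    clusters of size one, whose member's genome is necessarily the only
    source. Duplicate family names across libraries are prefixed with
    their library key.
    """
    if len(libraries) < 2:
        raise ValueError("clustering needs libraries from >= 2 genomes")
    pool: list[RepeatFamily] = []
    seen: dict[str, int] = {}
    for lib_name, fams in libraries.items():
        for fam in fams:
            name = fam.name
            if name in seen:
                name = f"{lib_name}:{name}"
            seen[name] = 1
            pool.append(RepeatFamily(name, fam.consensus, fam.source_genome, fam.subclass))
    pool.sort(key=lambda f: (-len(f.consensus), f.name))
    clusters: list[list[RepeatFamily]] = []
    for fam in pool:
        for cluster in clusters:
            rep = cluster[0]
            if _pair_identity(fam.consensus, rep.consensus) >= 100.0 * identity_threshold:
                cluster.append(fam)
                break
        else:
            clusters.append([fam])
    singletons = [c[0] for c in clusters if len(c) == 1]
    return clusters, singletons


# ---------------------------------------------------------------------------
# seeded cross-genome search


def _candidate_windows(query_codes, contig_codes, qlen, pad=_DIAG_PAD):
    """Candidate (start, end) windows on a contig sharing an exact seed."""
    qk, qv = sc.kmer_values(query_codes, _SEED_K)
    ck, cv = sc.kmer_values(contig_codes, _SEED_K)
    qvals = qk[qv]
    qpos = np.flatnonzero(qv)
    if qvals.size == 0 or ck.size == 0:
        return []
    order = np.argsort(qvals, kind="stable")
    qvals_s, qpos_s = qvals[order], qpos[order]
    cvals = ck[cv]
    cpos = np.flatnonzero(cv)
    lo = np.searchsorted(qvals_s, cvals, side="left")
    hi = np.searchsorted(qvals_s, cvals, side="right")
    counts = hi - lo
    sel = np.flatnonzero(counts)
    if sel.size == 0:
        return []
    g_rep = np.repeat(cpos[sel], counts[sel])
    q_rep = np.concatenate([qpos_s[lo[i] : hi[i]] for i in sel])
    diag = g_rep - q_rep
    order = np.argsort(g_rep, kind="stable")
    g_rep, diag = g_rep[order], diag[order]
    windows = []
    start_i = 0
    for i in range(1, g_rep.size + 1):
        if i == g_rep.size or g_rep[i] - g_rep[i - 1] > qlen:
            d = diag[start_i:i]
            ws = int(d.min()) - pad
            we = int(d.max()) + qlen + pad
            windows.append((max(0, ws), min(contig_codes.size, we)))
            start_i = i
    # merge overlapping windows
    merged = []
    for ws, we in sorted(windows):
        if merged and ws <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], we))
        else:
            merged.append((ws, we))
    return merged


def cross_genome_search(
    family,
    genome,
    min_identity: float = 70.0,
    family_name: str | None = None,
) -> list[GenomeHit]:
    """Locate copies of a consensus in a genome by seed-and-extend.

    ``family`` is a :class:`RepeatFamily`, a
    :class:`~viriscape.simgen.RepeatFamilySpec` (realized), or a plain
    sequence. Each candidate region found by exact 12-mer seeding is
    aligned end-free against the full consensus (both orientations);
    matches at >= ``min_identity`` percent identity over the consensus
    length are reported. Deterministic.
    """
    if isinstance(family, str):
        consensus, name = family, family_name or "query"
    else:
        consensus = getattr(family, "consensus", None)
        if consensus is None and hasattr(family, "realize"):
            consensus = family.realize()
        name = family_name or family.name
    seqs = genome.seqs if hasattr(genome, "seqs") else dict(genome)
    qlen = len(consensus)
    max_ed = int(np.floor(qlen * (1.0 - min_identity / 100.0)))
    queries = {"+": sc.encode(consensus), "-": sc.encode(sc.revcomp(consensus))}
    hits: list[GenomeHit] = []
    for contig, seq in seqs.items():
        contig_codes = sc.encode(seq)
        contig_hits: list[GenomeHit] = []
        for strand, qcodes in queries.items():
            for ws, we in _candidate_windows(qcodes, contig_codes, qlen):
                target = sc.decode(contig_codes[ws:we])
                query = consensus if strand == "+" else sc.revcomp(consensus)
                res = edlib.align(query, target, mode="HW", task="locations", k=max_ed)
                ed = res["editDistance"]
                if ed < 0:
                    continue
                loc = res["locations"][0]
                h_start = ws + (loc[0] or 0)
                h_end = ws + loc[1] + 1
                contig_hits.append(
                    GenomeHit(name, contig, h_start, h_end, 100.0 * (1.0 - ed / qlen))
                )
        # deduplicate overlapping hits (e.g. found on both strands): keep best
        contig_hits.sort(key=lambda h: (-h.pct_identity, h.start))
        kept: list[GenomeHit] = []
        for h in contig_hits:
            if any(min(h.end, k.end) - max(h.start, k.start) > 0.5 * h.length for k in kept):
                continue
            kept.append(h)
        hits.extend(sorted(kept, key=lambda h: h.start))
    return hits


# ---------------------------------------------------------------------------
# novelty verdicts


def is_novel(
    family,
    own_annotations,
    hits_in_other_genomes: dict[str, list[GenomeHit]],
    min_hit_len: int = 100,
    min_hit_identity: float = 80.0,
    min_abundance_bp: int = 5000,
    max_mean_div: float = 10.0,
) -> tuple[bool, list[str]]:
    """Apply the species-unique criteria to a singleton family.

    Novel iff no other genome has a hit >= ``min_hit_len`` bp at
    >= ``min_hit_identity`` percent identity, the family's own-genome
    annotated abundance is >= ``min_abundance_bp``, and the length-weighted
    mean divergence of its own copies is < ``max_mean_div`` percent.
    Returns (verdict, reasons).
    """
    name = family if isinstance(family, str) else family.name
    reasons = []
    for other, hits in hits_in_other_genomes.items():
        sig = [h for h in hits if h.length >= min_hit_len and h.pct_identity >= min_hit_identity]
        if sig:
            best = max(sig, key=lambda h: h.pct_identity)
            reasons.append(
                f"significant hit in {other}: {best.length} bp at {best.pct_identity:.1f}% identity"
            )
    own = [a for a in own_annotations if a.family == name]
    abundance = sum(a.length for a in own)
    if abundance < min_abundance_bp:
        reasons.append(f"own-genome abundance {abundance} bp < {min_abundance_bp} bp")
    if own:
        mean_div = float(np.average([a.pct_div for a in own], weights=[a.length for a in own]))
        if mean_div >= max_mean_div:
            reasons.append(f"mean copy divergence {mean_div:.1f}% >= {max_mean_div}%")
    else:
        reasons.append("no annotated copies in own genome")
    if not reasons:
        return True, ["passes all species-unique criteria"]
    return False, reasons


def novel_family_report(
    libraries: dict[str, list[RepeatFamily]],
    genomes: dict[str, object],
    annotations: dict[str, list],
    identity_threshold: float = 0.90,
    **novel_kwargs,
) -> pd.DataFrame:
    """End-to-end species-unique detection across genomes.

    Clusters the libraries, searches every singleton against the other
    genomes, and applies :func:`is_novel`. Returns one row per singleton.
    """
    _, singletons = cluster_families(libraries, identity_threshold)
    rows = []
    for fam in singletons:
        others = {g: genomes[g] for g in genomes if g != fam.source_genome}
        hits = {g: cross_genome_search(fam, genome) for g, genome in others.items()}
        verdict, reasons = is_novel(
            fam, annotations[fam.source_genome], hits, **novel_kwargs
        )
        rows.append(
            {
                "family": fam.name,
                "source_genome": fam.source_genome,
                "consensus_length": len(fam.consensus),
                "novel": verdict,
                "reasons": "; ".join(reasons),
            }
        )
    return pd.DataFrame(
        rows, columns=["family", "source_genome", "consensus_length", "novel", "reasons"]
    )


# ---------------------------------------------------------------------------
# polymorphic tandem-array insertions


def eligible_isolated_loci(
    loci: pd.DataFrame,
    annotations,
    family: str,
    isolation: int = 1000,
) -> pd.DataFrame:
    """Keep loci with no non-family annotation within ``isolation`` bp.

    A locus at a contig edge with no neighbors qualifies (the edge counts
    as empty).
    """
    others = [a for a in annotations if a.family != family]
    keep = []
    for _, row in loci.iterrows():
        lo = row["start"] - isolation
        hi = row["end"] + isolation
        crowded = any(
            a.chrom == row["chrom"] and a.start < hi and a.end > lo for a in others
        )
        keep.append(not crowded)
    return loci[np.array(keep, dtype=bool)].reset_index(drop=True)


def flank_signature(genome, locus, flank: int = 100) -> str:
    """Concatenated left+right flanks of a locus: the intact-site probe.

    ``locus`` is (chrom, start, end) or a locus-table row. Raises
    ``ValueError`` when the contig has fewer than ``flank`` bp on either
    side.
    """
    if hasattr(locus, "keys"):
        chrom, start, end = locus["chrom"], int(locus["start"]), int(locus["end"])
    else:
        chrom, start, end = locus
    seqs = genome.seqs if hasattr(genome, "seqs") else genome
    seq = seqs[chrom]
    if start - flank < 0 or end + flank > len(seq):
        raise ValueError(
            f"locus {chrom}:{start}-{end} has < {flank} bp of flank within its contig"
        )
    return seq[start - flank : start] + seq[end : end + flank]


def site_intact(probe: str, other_genome, min_identity: float = 90.0) -> str:
    """Is the insertion site intact (empty) in another genome?

    ``intact``: exactly one continuous hit covering the full probe at
    >= ``min_identity`` percent identity. ``ambiguous``: multiple
    qualifying hits (paralogy). ``not_intact``: none — e.g. the other
    genome carries the same insertion, splitting the junction probe.
    """
    hits = cross_genome_search(probe, other_genome, min_identity=min_identity, family_name="probe")
    qualifying = [h for h in hits if h.pct_identity >= min_identity]
    if len(qualifying) == 1:
        return "intact"
    if len(qualifying) > 1:
        return "ambiguous"
    return "not_intact"


def call_polymorphic_insertions(
    genomes: dict[str, object],
    annotations: dict[str, list],
    family: str,
    merge_gap: int = 100,
    isolation: int = 1000,
    flank: int = 100,
    min_identity: float = 90.0,
) -> pd.DataFrame:
    """Call family insertions present in one genome and absent in all others.

    For each focal genome, isolated loci of ``family`` are probed by their
    flank signature; an insertion is called when the probe site is intact
    in *every* other genome. Loci with insufficient flank are skipped with
    a recorded reason. The host-gene annotation hook is left null.
    """
    rows = []
    for focal in genomes:
        loci, _ = tandem_array_stats(annotations[focal], family, merge_gap)
        if len(loci) == 0:
            continue
        eligible = eligible_isolated_loci(loci, annotations[focal], family, isolation)
        for _, locus in eligible.iterrows():
            try:
                probe = flank_signature(genomes[focal], locus, flank)
            except ValueError as err:
                rows.append(
                    {
                        "focal_genome": focal,
                        "chrom": locus["chrom"],
                        "start": int(locus["start"]),
                        "end": int(locus["end"]),
                        "array_length": int(locus["length"]),
                        "called": False,
                        "detail": str(err),
                        "host_gene": None,
                    }
                )
                continue
            verdicts = {
                other: site_intact(probe, genomes[other], min_identity)
                for other in genomes
                if other != focal
            }
            called = all(v == "intact" for v in verdicts.values())
            rows.append(
                {
                    "focal_genome": focal,
                    "chrom": locus["chrom"],
                    "start": int(locus["start"]),
                    "end": int(locus["end"]),
                    "array_length": int(locus["length"]),
                    "called": called,
                    "detail": ";".join(f"{g}={v}" for g, v in verdicts.items()),
                    "host_gene": None,
                }
            )
    cols = ["focal_genome", "chrom", "start", "end", "array_length", "called", "detail", "host_gene"]
    return pd.DataFrame(rows, columns=cols)
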