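"""Alignment-segment IO, an internal anchor aligner, and segment filters.

Whole-genome comparisons are represented as lists of
:class:`AlignmentSegment` — near-colinear matches between a reference and a
query genome. Segments can be read from a NUCmer ``show-coords -T -l -c``
style table, or computed internally for synthetic genome pairs by chaining
unique exact k-mer anchors (so tests need no external aligner).

Coordinates are 0-based half-open internally; the coords-table dialect is
1-based inclusive with reversed query coordinates encoding the minus
strand, converted at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _seqcodes as sc

__all__ = [
    "AlignmentSegment",
    "read_coords_table",
    "write_coords_table",
    "anchor_align",
    "filter_segments",
    "write_segments_bed",
]


@dataclass
class AlignmentSegment:
    """One gap-free/near-colinear match between reference and query."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    strand: str
    pct_identity: float

    def __post_init__(self):
        if self.ref_start >= self.ref_end:
            raise ValueError("ref_start must be < ref_end")
        if self.qry_start >= self.qry_end:
            raise ValueError("qry_start must be < qry_end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity must be within [0, 100]")

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def qry_span(self) -> int:
        return self.qry_end - self.qry_start

    @property
    def match_len(self) -> int:
        """Raw match length proxy: the smaller of the two spans."""
        return min(self.ref_span, self.qry_span)


# ---------------------------------------------------------------------------
# coords-table dialect


def read_coords_table(path) -> list[AlignmentSegment]:
    """Read a tab-delimited show-coords-style table.

    Columns: ref_start, ref_end, qry_start, qry_end, ref_len, qry_len,
    pct_idy, ref_chrom, qry_chrom (1-based inclusive; reversed query
    coordinates encode the minus strand).
    """
    segments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-delimited columns")
            try:
                rs, re_, qs, qe = (int(x) for x in fields[:4])
                idy = float(fields[6])
                rc, qc = fields[7], fields[8]
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed row ({err})") from None
            strand = "+"
            if qs > qe:
                strand = "-"
                qs, qe = qe, qs
            segments.append(
                AlignmentSegment(rc, rs - 1, re_, qc, qs - 1, qe, strand, idy)
            )
    return segments


def write_coords_table(segments, path) -> None:
    """Inverse of :func:`read_coords_table` (round-trips bit-exactly)."""
    with open(path, "w") as fh:
        for s in segments:
            qs, qe = s.qry_start + 1, s.qry_end
            if s.strand == "-":
                qs, qe = qe, qs
            fh.write(
                f"{s.ref_start + 1}\t{s.ref_end}\t{qs}\t{qe}\t"
                f"{s.ref_span}\t{s.qry_span}\t{s.pct_identity:.2f}\t"
                f"{s.ref_chrom}\t{s.qry_chrom}\n"
            )


def write_segments_bed(segments, path) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(segments):
            fh.write(
                f"{s.ref_chrom}\t{s.ref_start}\t{s.ref_end}\tseg{i};"
                f"{s.qry_chrom}:{s.qry_start}-{s.qry_end}\t"
                f"{s.pct_identity:.1f}\t{s.strand}\n"
            )


# ---------------------------------------------------------------------------
# internal anchor aligner


def _unique_canonical_kmers(seqs: dict[str, str], k: int):
    """Canonical k-mers occurring exactly once in the genome.

    Returns (values, contig_idx, pos, fwd) arrays sorted by value, plus the
    contig-name list.
    """
    names = list(seqs)
    vals_l, ci_l, pos_l, fwd_l = [], [], [], []
    for idx, name in enumerate(names):
        codes = sc.encode(seqs[name])
        canon, fwd, valid = sc.canonical_kmer_values(codes, k)
        if canon.size == 0:
            continue
        keep = np.flatnonzero(valid)
        vals_l.append(canon[keep])
        pos_l.append(keep.astype(np.int64))
        fwd_l.append(fwd[keep])
        ci_l.append(np.full(keep.size, idx, dtype=np.int32))
    if not vals_l:
        empty = np.empty(0, dtype=np.uint64)
        return empty, np.empty(0, np.int32), np.empty(0, np.int64), np.empty(0, bool), names
    vals = np.concatenate(vals_l)
    ci = np.concatenate(ci_l)
    pos = np.concatenate(pos_l)
    fwd = np.concatenate(fwd_l)
    order = np.argsort(vals, kind="stable")
    vals, ci, pos, fwd = vals[order], ci[order], pos[order], fwd[order]
    uniq, start, counts = np.unique(vals, return_index=True, return_counts=True)
    single = counts == 1
    sel = start[single]
    return vals[sel], ci[sel], pos[sel], fwd[sel], names


def _chain_anchors(ref_pos, qry_pos, k, orient, chain_gap):
    """Split ref-sorted anchors of one orientation into colinear chains."""
    chains = []
    if ref_pos.size == 0:
        return chains
    start = 0
    for i in range(1, ref_pos.size):
        rgap = ref_pos[i] - ref_pos[i - 1]
        qstep = qry_pos[i] - qry_pos[i - 1]
        ok = rgap <= chain_gap
        if orient == "+":
            ok = ok and 0 < qstep <= chain_gap
        else:
            ok = ok and -chain_gap <= qstep < 0
        if not ok:
            chains.append((start, i))
            start = i
    chains.append((start, ref_pos.size))
    return chains


def _anchor_coverage(ref_pos, k) -> int:
    """Bases of the reference span covered by the union of anchor windows."""
    if ref_pos.size == 0:
        return 0
    gaps = np.diff(ref_pos)
    return int(np.minimum(gaps, k).sum() + k)


def anchor_align(
    genome_a,
    genome_b,
    anchor_k: int = 20,
    chain_gap: int = 5000,
) -> list[AlignmentSegment]:
    """Align two genomes by chaining unique exact k-mer anchors.

    K-mers unique (single-copy, canonical) in *both* genomes become
    anchors; colinear anchors of consistent orientation within
    ``chain_gap`` on both sequences are chained into segments. Segment
    identity is the fraction of the reference span covered by anchors, a
    lower bound on true identity. Designed for the low-divergence synthetic
    genome pairs produced by :mod:`viriscape.simgen`.
    """
    if anchor_k < 12:
        raise ValueError("anchor_k < 12 yields spurious matches; use k >= 12")
    seqs_a = genome_a.seqs if hasattr(genome_a, "seqs") else dict(genome_a)
    seqs_b = genome_b.seqs if hasattr(genome_b, "seqs") else dict(genome_b)
    va, ca, pa, fa, names_a = _unique_canonical_kmers(seqs_a, anchor_k)
    vb, cb, pb, fb, names_b = _unique_canonical_kmers(seqs_b, anchor_k)
    if va.size == 0 or vb.size == 0:
        return []
    common, ia, ib = np.intersect1d(va, vb, assume_unique=True, return_indices=True)
    if common.size == 0:
        return []
    rc_i, rp, rf = ca[ia], pa[ia], fa[ia]
    qc_i, qp, qf = cb[ib], pb[ib], fb[ib]
    orient = np.where(rf == qf, ord("+"), ord("-")).astype(np.uint8)

    segments = []
    # group by (ref contig, qry contig, orientation)
    key = (rc_i.astype(np.int64) << 33) | (qc_i.astype(np.int64) << 1) | (orient == ord("-"))
    order = np.lexsort((rp, key))
    key_s, rp_s, qp_s = key[order], rp[order], qp[order]
    rc_s, qc_s, or_s = rc_i[order], qc_i[order], orient[order]
    bounds = np.flatnonzero(np.diff(key_s)) + 1
    group_starts = np.concatenate(([0], bounds))
    group_ends = np.concatenate((bounds, [key_s.size]))
    for gs, ge in zip(group_starts, group_ends):
        o = "+" if or_s[gs] == ord("+") else "-"
        r = rp_s[gs:ge]
        q = qp_s[gs:ge]
        for cs, ce in _chain_anchors(r, q, anchor_k, o, chain_gap):
            rr, qq = r[cs:ce], q[cs:ce]
            ref_start = int(rr[0])
            ref_end = int(rr[-1]) + anchor_k
            qry_start = int(qq.min())
            qry_end = int(qq.max()) + anchor_k
            covered = _anchor_coverage(rr, anchor_k)
            idy = 100.0 * covered / (ref_end - ref_start)
            segments.append(
                AlignmentSegment(
                    names_a[rc_s[gs]], ref_start, ref_end,
                    names_b[qc_s[gs]], qry_start, qry_end,
                    o, min(idy, 100.0),
                )
            )

    # resolve reference-overlapping chains: keep the longer, deterministically
    segments.sort(key=lambda s: (-s.ref_span, s.ref_start, s.qry_start, s.strand))
    accepted: list[AlignmentSegment] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for s in segments:
        ivs = occupied.setdefault(s.ref_chrom, [])
        overlap = 0
        for a, b in ivs:
            overlap += max(0, min(b, s.ref_end) - max(a, s.ref_start))
        if overlap > 0.5 * s.ref_span:
            continue
        ivs.append((s.ref_start, s.ref_end))
        accepted.append(s)
    accepted.sort(key=lambda s: (s.ref_chrom, s.ref_start, s.ref_end))
    return accepted


# ---------------------------------------------------------------------------
# filters


def filter_segments(
    segments,
    min_match: int = 100,
    min_identity: float = 90.0,
    min_span: int = 1000,
) -> list[AlignmentSegment]:
    """Two-stage segment filter.

    Stage one drops segments whose raw match length is below ``min_match``;
    stage two drops segments below ``min_identity`` percent identity or
    spanning less than ``min_span`` bp in *either* the reference or the
    query. Order is preserved and the filter is idempotent.
    """
    out = []
    for s in segments:
        if s.match_len < min_match:
            continue
        if s.pct_identity < min_identity:
            continue
        if min(s.ref_span, s.qry_span) < min_span:
            continue
        out.append(s)
    return out
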