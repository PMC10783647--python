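"""Orientation blocks, inversion-breakpoint intervals, and sharing status.

Filtered alignment segments along a chromosome are grouped into
*orientation blocks*: maximal runs of same-strand segments whose query
coordinates progress monotonically (ascending for ``+``, descending for
``-``). A strand flip between adjacent blocks bounds an inversion; the
unaligned gap between the flanking blocks is the breakpoint interval and
its width is the breakpoint resolution. Monotonicity breaks *without* a
strand flip (translocations) split blocks but are reported separately,
not as inversion breakpoints.

Nested inversions need no special handling here: re-inverted inner
intervals alternate strand in reference coordinates, so their boundaries
surface as ordinary block transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "OrientationBlock",
    "BreakpointInterval",
    "build_blocks",
    "call_breakpoints",
    "call_inversions",
    "classify_sharing",
    "write_breakpoints_bed",
]


@dataclass
class OrientationBlock:
    ref_chrom: str
    ref_start: int
    ref_end: int
    strand: str
    segments: list = field(default_factory=list)
    qry_direction_consistent: bool = True

    @property
    def n_segments(self) -> int:
        return len(self.segments)


@dataclass
class BreakpointInterval:
    """Gap between adjacent opposite-orientation blocks."""

    ref_chrom: str
    start: int
    end: int
    left_block: OrientationBlock | None = None
    right_block: OrientationBlock | None = None

    @property
    def resolution(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """Inclusive containment (a width-0 interval contains its point)."""
        return self.start <= pos <= self.end


def build_blocks(segments, max_intra_gap: int = 50_000) -> list[OrientationBlock]:
    """Group one chromosome pair's segments into orientation blocks.

    Segments must come pre-filtered (see :func:`viriscape.alignio.
    filter_segments`) and from a single reference/query chromosome pair.
    A new block starts at every strand change, at every query-monotonicity
    break, and whenever the reference gap exceeds ``max_intra_gap``.
    """
    segments = sorted(segments, key=lambda s: (s.ref_start, s.ref_end))
    if not segments:
        return []
    ref_chroms = {s.ref_chrom for s in segments}
    qry_chroms = {s.qry_chrom for s in segments}
    if len(ref_chroms) > 1 or len(qry_chroms) > 1:
        raise ValueError(
            f"segments span multiple chromosomes (ref {sorted(ref_chroms)}, "
            f"qry {sorted(qry_chroms)}); build blocks per chromosome pair"
        )

    blocks: list[OrientationBlock] = []
    run = [segments[0]]
    for prev, cur in zip(segments, segments[1:]):
        same_strand = cur.strand == prev.strand
        close = cur.ref_start - prev.ref_end <= max_intra_gap
        if same_strand:
            if cur.strand == "+":
                monotone = cur.qry_start >= prev.qry_end - _slack(prev, cur)
            else:
                monotone = cur.qry_end <= prev.qry_start + _slack(prev, cur)
        else:
            monotone = False
        if same_strand and close and monotone:
            run.append(cur)
        else:
            blocks.append(_finish(run))
            run = [cur]
    blocks.append(_finish(run))
    return blocks


def _slack(prev, cur) -> int:
    # tolerate small query-side overlap from anchor-chain trimming
    return min(prev.qry_span, cur.qry_span) // 2


def _finish(run) -> OrientationBlock:
    return OrientationBlock(
        ref_chrom=run[0].ref_chrom,
        ref_start=run[0].ref_start,
        ref_end=max(s.ref_end for s in run),
        strand=run[0].strand,
        segments=list(run),
    )


def call_breakpoints(blocks, junction_guard: int = 0) -> list[BreakpointInterval]:
    """One breakpoint interval per adjacent opposite-strand block pair.

    The interval is ``[left.ref_end, right.ref_start]``; when blocks abut
    or overlap it collapses to width 0 at the shared boundary.

    ``junction_guard`` widens each side by a fixed margin to absorb
    micro-homology at the junction: a stretch that reads identically in
    both orientations lets an aligned block overrun the physical
    breakpoint by up to the homology length, so pipelines built on exact
    k-mer anchors should pass their anchor size here (longer chance
    homology has probability ~4^-k).
    """
    out = []
    ordered = sorted(blocks, key=lambda b: (b.ref_start, b.ref_end))
    for left, right in zip(ordered, ordered[1:]):
        if left.strand == right.strand:
            continue
        s, e = left.ref_end, right.ref_start
        if e < s:
            s = e = (s + e) // 2
        s = max(0, s - junction_guard)
        e = e + junction_guard
        out.append(BreakpointInterval(left.ref_chrom, s, e, left, right))
    return out


def call_inversions(blocks) -> list[tuple[str, BreakpointInterval, BreakpointInterval]]:
    """Pair breakpoints flanking each minus-strand block into inversions.

    Returns (chrom, left breakpoint interval, right breakpoint interval)
    per inverted block that is bounded by plus-strand neighbors on both
    sides. Inversions truncated by the end of the aligned region are
    skipped (their second boundary is unobserved).
    """
    ordered = sorted(blocks, key=lambda b: (b.ref_start, b.ref_end))
    bkpts = call_breakpoints(ordered)
    by_left = {id(b.left_block): b for b in bkpts}
    by_right = {id(b.right_block): b for b in bkpts}
    out = []
    for blk in ordered:
        if blk.strand != "-":
            continue
        left = by_right.get(id(blk))
        right = by_left.get(id(blk))
        if left is not None and right is not None:
            out.append((blk.ref_chrom, left, right))
    return out


def classify_sharing(
    inversions_by_strain: dict[str, list[tuple[str, float, float]]],
    match_tol: int = 1000,
    references: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Match inversions across strains and label each fixed or polymorphic.

    ``inversions_by_strain`` maps strain name to a list of
    ``(chrom, left_boundary, right_boundary)`` tuples on a common
    reference (boundaries are breakpoint-interval midpoints). Two
    inversions match when both boundaries agree within ``match_tol`` bp.
    An inversion observed in every strain is *fixed*; in a proper subset,
    *polymorphic*.
    """
    if len(inversions_by_strain) < 2:
        raise ValueError("sharing classification needs >= 2 strains")
    if references is not None and len(set(references.values())) > 1:
        raise ValueError(
            f"breakpoint sets are on different references: {sorted(set(references.values()))}"
        )
    entries = []  # (strain, chrom, left, right)
    for strain, invs in inversions_by_strain.items():
        for chrom, left, right in invs:
            entries.append((strain, chrom, float(left), float(right)))

    parent = list(range(len(entries)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            si, ci, li, ri = entries[i]
            sj, cj, lj, rj = entries[j]
            if ci == cj and abs(li - lj) <= match_tol and abs(ri - rj) <= match_tol:
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(entries)):
        clusters.setdefault(find(i), []).append(i)

    all_strains = set(inversions_by_strain)
    rows = []
    for n, members in enumerate(sorted(clusters.values(), key=lambda m: (entries[m[0]][1], entries[m[0]][2]))):
        strains = sorted({entries[i][0] for i in members})
        chrom = entries[members[0]][1]
        left = min(entries[i][2] for i in members)
        right = max(entries[i][3] for i in members)
        rows.append(
            {
                "inversion_id": f"inv{n}",
                "chrom": chrom,
                "left": left,
                "right": right,
                "strains": ",".join(strains),
                "n_strains": len(strains),
                "status": "fixed" if set(strains) == all_strains else "polymorphic",
            }
        )
    return pd.DataFrame(rows)


def write_breakpoints_bed(breakpoints, path) -> None:
    """BED export; name is the breakpoint id, score its resolution."""
    with open(path, "w") as fh:
        for i, b in enumerate(breakpoints):
            end = max(b.end, b.start + 1)  # BED needs non-empty intervals
            fh.write(f"{b.ref_chrom}\t{b.start}\t{end}\tbkpt{i}\t{b.resolution}\n")
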