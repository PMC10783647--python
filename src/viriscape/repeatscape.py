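"""Repeat-annotation tables: proportions, landscapes, densities, arrays.

Consumes RepeatMasker-style ``.out`` tables (we do not run the masker) and
computes the descriptive statistics used to compare repeat complements
between genomes:

* genome proportions by subclass, per contig-class partition (e.g. whole
  genome vs Y-called contigs), with overlapping same-subclass hits merged
  so no base is counted twice;
* divergence landscapes — annotated bp binned by percent divergence of
  each copy from its family consensus (a proxy for insertion age), using
  plain length-sum semantics;
* per-window densities across chromosomes;
* tandem-array (ITR) locus statistics, merging nearby hits of one family
  into loci.

The masker-reported divergence column is used as-is (no Kimura
correction). The overlap policy deliberately differs between proportions
(merged) and landscapes (length-sum), matching the semantics of the usual
parsing tools; both are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RepeatAnnotation",
    "read_masker_out",
    "write_masker_out",
    "annotations_from_truth",
    "genome_proportions",
    "divergence_landscape",
    "window_density",
    "tandem_array_stats",
    "merge_intervals",
]


@dataclass
class RepeatAnnotation:
    """One masked repeat hit (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    family: str
    subclass: str
    pct_div: float
    strand: str = "+"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("annotation end must exceed start")
        if self.pct_div < 0:
            raise ValueError("pct_div must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# masker-out IO


def read_masker_out(path) -> list[RepeatAnnotation]:
    """Parse a RepeatMasker ``.out`` table.

    Handles the standard 3-line header and whitespace-delimited columns:
    score, %div, %del, %ins, query, begin, end, (left), strand (+/C),
    repeat family, class/family, ... Coordinates are converted from
    1-based inclusive; a ``C`` strand becomes ``-``.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue
            low = s.lower()
            if low.startswith(("sw", "score", "there were no")):
                continue
            fields = s.split()
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: expected >= 11 columns, got {len(fields)}")
            try:
                pct_div = float(fields[1])
                chrom = fields[4]
                begin = int(fields[5].replace(",", ""))
                end = int(fields[6].replace(",", ""))
                strand = "-" if fields[8] in ("C", "-") else "+"
                family = fields[9]
                subclass = fields[10]
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed row ({err})") from None
            out.append(
                RepeatAnnotation(chrom, begin - 1, end, family, subclass, pct_div, strand)
            )
    return out


def write_masker_out(annotations, path) -> None:
    """Write annotations in the masker ``.out`` dialect (for fixtures/round-trips)."""
    with open(path, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query     position in query    matching"
            "  repeat        position in repeat\n"
            "score  div. del. ins.  sequence  begin  end   (left)  repeat"
            "  class/family  begin end (left) ID\n\n"
        )
        for i, a in enumerate(annotations, 1):
            strand = "C" if a.strand == "-" else "+"
            fh.write(
                f"{1000:5d} {a.pct_div:5.1f}  0.0  0.0  {a.chrom} "
                f"{a.start + 1} {a.end} (0) {strand} {a.family} {a.subclass} "
                f"1 {a.length} (0) {i}\n"
            )


def annotations_from_truth(truth) -> list[RepeatAnnotation]:
    """Convert a simulation truth ledger into annotation records.

    Divergence targets become the reported percent divergence, so planted
    landscapes are exact in expectation.
    """
    return [
        RepeatAnnotation(
            r.chrom, r.start, r.end, r.family, r.subclass, 100.0 * r.divergence
        )
        for r in truth.planted_repeats
    ]


# ---------------------------------------------------------------------------
# interval helpers


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Union of (start, end) half-open intervals."""
    ivs = sorted(intervals)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _merged_bp(annots) -> int:
    by_chrom: dict[str, list] = {}
    for a in annots:
        by_chrom.setdefault(a.chrom, []).append((a.start, a.end))
    return sum(e - s for ivs in by_chrom.values() for s, e in merge_intervals(ivs))


# ---------------------------------------------------------------------------
# statistics


def genome_proportions(
    annotations,
    genome_lengths: dict[str, int],
    partition: dict[str, str] | None = None,
    merge_overlaps: bool = True,
) -> pd.DataFrame:
    """Annotated bp and percent of partition per repeat subclass.

    ``partition`` maps contig to a class label (e.g. A/X/Y); by default the
    whole genome is one partition. With ``merge_overlaps`` (default),
    overlapping same-subclass hits are merged before summing so no base is
    double-counted and percentages per partition sum to <= 100.
    """
    part = partition or {c: "genome" for c in genome_lengths}
    for a in annotations:
        if a.chrom not in genome_lengths:
            raise ValueError(f"annotation on unknown contig {a.chrom!r}")
    part_bp: dict[str, int] = {}
    for contig, length in genome_lengths.items():
        part_bp[part.get(contig, "genome")] = part_bp.get(part.get(contig, "genome"), 0) + length

    groups: dict[tuple[str, str], list] = {}
    for a in annotations:
        key = (part.get(a.chrom, "genome"), a.subclass)
        groups.setdefault(key, []).append(a)

    rows = []
    for (pclass, subclass), annots in sorted(groups.items()):
        bp = _merged_bp(annots) if merge_overlaps else sum(a.length for a in annots)
        rows.append(
            {
                "partition": pclass,
                "subclass": subclass,
                "bp": bp,
                "pct": 100.0 * bp / part_bp[pclass],
            }
        )
    return pd.DataFrame(rows, columns=["partition", "subclass", "bp", "pct"])


def divergence_landscape(
    annotations,
    genome_length: int,
    bin_width: float = 1.0,
    max_div: float = 50.0,
    values: str = "fraction",
) -> pd.DataFrame:
    """Divergence landscape: bin x subclass matrix of annotated mass.

    Each annotation's full length lands in bin ``floor(pct_div /
    bin_width)`` (length-sum semantics; overlaps are not merged, so column
    sums equal total annotated bp per subclass). ``values`` selects
    ``"bp"`` or ``"fraction"`` of ``genome_length``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if values not in ("bp", "fraction"):
        raise ValueError("values must be 'bp' or 'fraction'")
    n_bins = int(np.ceil(max_div / bin_width))
    subclasses = sorted({a.subclass for a in annotations})
    mat = pd.DataFrame(
        0.0,
        index=pd.Index(np.arange(n_bins) * bin_width, name="div_bin"),
        columns=subclasses,
    )
    for a in annotations:
        b = min(int(a.pct_div // bin_width), n_bins - 1)
        mat.iloc[b, mat.columns.get_loc(a.subclass)] += a.length
    if values == "fraction":
        mat /= float(genome_length)
    return mat


def window_density(
    annotations,
    chrom_lengths: dict[str, int],
    window: int = 100_000,
) -> pd.DataFrame:
    """Annotated bp per window per subclass, apportioned by overlap.

    An annotation straddling a window boundary contributes to each window
    exactly the bp it overlaps, so per-chromosome sums conserve total
    annotated length.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    acc: dict[tuple[str, int, str], int] = {}
    for a in annotations:
        if a.chrom not in chrom_lengths:
            raise ValueError(f"annotation on unknown contig {a.chrom!r}")
        w0 = a.start // window
        w1 = (a.end - 1) // window
        for w in range(w0, w1 + 1):
            ws, we = w * window, (w + 1) * window
            ov = min(a.end, we) - max(a.start, ws)
            key = (a.chrom, w, a.subclass)
            acc[key] = acc.get(key, 0) + ov
    rows = [
        {
            "chrom": chrom,
            "start": w * window,
            "end": min((w + 1) * window, chrom_lengths[chrom]),
            "subclass": subclass,
            "bp": bp,
        }
        for (chrom, w, subclass), bp in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "subclass", "bp"])


def tandem_array_stats(
    annotations,
    family: str,
    merge_gap: int = 100,
) -> tuple[pd.DataFrame, dict]:
    """Merge one family's hits into loci and summarize array lengths.

    Hits of ``family`` within ``merge_gap`` bp of each other on the same
    contig are merged into a single locus. Returns the locus table and a
    summary with locus count, mean/total length.
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    by_chrom: dict[str, list] = {}
    for a in annotations:
        if a.family == family:
            by_chrom.setdefault(a.chrom, []).append((a.start, a.end))
    rows = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        merged = []
        for s, e in ivs[1:]:
            if s - cur_e <= merge_gap:
                cur_e = max(cur_e, e)
            else:
                merged.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((cur_s, cur_e))
        for s, e in merged:
            rows.append({"chrom": chrom, "start": s, "end": e, "length": e - s})
    loci = pd.DataFrame(rows, columns=["chrom", "start", "end", "length"])
    summary = {
        "family": family,
        "n_loci": len(loci),
        "mean_length": float(loci["length"].mean()) if len(loci) else float("nan"),
        "total_bp": int(loci["length"].sum()) if len(loci) else 0,
    }
    return loci, summary
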