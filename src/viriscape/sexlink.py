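"""Y-contig identification from sexed read k-mers and coverage ratios.

Two independent lines of evidence assign assembly contigs to chromosome
classes:

* **k-mer exclusion** — canonical 15-mers occurring exactly once in the
  whole assembly ("single-copy" k-mers) are tested for presence in a
  female read set; Y-derived contigs, absent from females, show a high
  percentage of single-copy k-mers unmatched by female reads;
* **coverage** — the female/male per-contig mean-depth ratio is expected
  near 0 for the Y, near 1 for autosomes, and near 2 for the X.

The decision rule combining the two is configurable via
:class:`Thresholds` and recorded in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _seqcodes as sc

__all__ = [
    "KmerSet",
    "Thresholds",
    "count_read_kmers",
    "contig_kmer_stats",
    "coverage_from_mapping_table",
    "build_profiles",
    "classify_contigs",
    "class_lengths",
]

_CHUNK_BASES = 16_000_000


@dataclass
class KmerSet:
    """A set of canonical k-mers held as a sorted uint64 array."""

    k: int
    values: np.ndarray
    source: str = ""

    def __len__(self) -> int:
        return int(self.values.size)

    def __contains__(self, kmer: str) -> bool:
        if len(kmer) != self.k:
            raise ValueError(f"k-mer length {len(kmer)} != k={self.k}")
        canon, _, valid = sc.canonical_kmer_values(sc.encode(kmer), self.k)
        if not valid[0]:
            return False
        return bool(self.contains_values(canon[:1])[0])

    def contains_values(self, vals: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.values, vals)
        idx = np.minimum(idx, max(self.values.size - 1, 0))
        if self.values.size == 0:
            return np.zeros(vals.size, dtype=bool)
        return self.values[idx] == vals


def _check_k(k: int) -> None:
    if k % 2 == 0:
        raise ValueError("k must be odd (even k makes canonicalization ambiguous)")
    if not 11 <= k <= 31:
        raise ValueError("k must be within [11, 31]")


def _kmers_from_buffer(codes: np.ndarray, k: int) -> np.ndarray:
    canon, _, valid = sc.canonical_kmer_values(codes, k)
    return canon[valid]


def _iter_read_buffers(reads, qual_cutoff: int):
    """Yield uint8 code buffers with low-quality/ambiguous bases set to 4
    and reads separated by a sentinel 4, in chunks of bounded size."""
    buf: list[np.ndarray] = []
    size = 0

    def emit():
        nonlocal buf, size
        if buf:
            yield np.concatenate(buf)
        buf, size = [], 0

    sep = np.array([4], dtype=np.uint8)
    for seq, qual in reads:
        codes = sc.encode(seq)
        if qual is not None:
            q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
            codes = codes.copy()
            codes[q < qual_cutoff] = 4
        buf.append(codes)
        buf.append(sep)
        size += codes.size + 1
        if size >= _CHUNK_BASES:
            yield from emit()
    yield from emit()


def _readset_buffers(reads):
    """Code buffers straight from a ReadSet's matrices (constant max quality)."""
    for _, _, codes in reads.chunks:
        n, rl = codes.shape
        rows = max(1, _CHUNK_BASES // (rl + 1))
        for i in range(0, n, rows):
            block = codes[i : i + rows]
            padded = np.full((block.shape[0], rl + 1), 4, dtype=np.uint8)
            padded[:, :rl] = block
            yield padded.ravel()


def _reads_as_pairs(reads):
    """Normalize the accepted read inputs to (seq, qual-or-None) pairs."""
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        import pysam

        with pysam.FastxFile(str(reads)) as fh:
            for rec in fh:
                yield rec.sequence, rec.quality
        return
    yield from reads


def count_read_kmers(reads, k: int = 15, qual_cutoff: int = 5) -> KmerSet:
    """Canonical k-mer set of a read collection.

    ``reads`` may be a :class:`~viriscape.simgen.ReadSet`, a FASTQ path, or
    an iterable of ``(sequence, quality-string-or-None)`` pairs. K-mer
    windows covering an ambiguous base or a base with Phred quality below
    ``qual_cutoff`` are excluded; the remainder are canonicalized.
    """
    _check_k(k)
    from .simgen import ReadSet

    if isinstance(reads, ReadSet):
        buffers = _readset_buffers(reads)
    else:
        buffers = _iter_read_buffers(_reads_as_pairs(reads), qual_cutoff)
    partials: list[np.ndarray] = []
    for buf in buffers:
        vals = _kmers_from_buffer(buf, k)
        if vals.size:
            partials.append(np.unique(vals))
    if not partials:
        return KmerSet(k, np.empty(0, dtype=np.uint64), source="reads")
    values = np.unique(np.concatenate(partials))
    return KmerSet(k, values, source="reads")


# ---------------------------------------------------------------------------
# assembly scanning


def contig_kmer_stats(assembly, female: KmerSet, k: int = 15) -> pd.DataFrame:
    """Per-contig single-copy k-mer statistics against a female k-mer set.

    For each contig: *unique* k-mers are its distinct canonical k-mers;
    *single-copy* k-mers are those occurring exactly once across the whole
    assembly; ``pct_unmatched_female`` is the percentage of the contig's
    single-copy k-mers absent from the female read set. Contigs shorter
    than ``k`` get zero denominators and NaN percentages.
    """
    _check_k(k)
    if female.k != k:
        raise ValueError(f"female k-mer set has k={female.k}, expected {k}")
    seqs = assembly.seqs if hasattr(assembly, "seqs") else dict(assembly)
    per_contig: dict[str, np.ndarray] = {}
    for name, seq in seqs.items():
        per_contig[name] = _kmers_from_buffer(sc.encode(seq), k)
    if per_contig:
        allvals = np.concatenate([v for v in per_contig.values()])
    else:
        allvals = np.empty(0, dtype=np.uint64)
    uniq, counts = np.unique(allvals, return_counts=True)
    single_copy = uniq[counts == 1]

    rows = []
    for name, seq in seqs.items():
        vals = np.unique(per_contig[name])
        n_unique = int(vals.size)
        if n_unique == 0:
            rows.append(
                {
                    "contig": name, "length": len(seq), "n_unique_kmers": 0,
                    "n_single_copy": 0, "pct_single_copy": np.nan,
                    "pct_unmatched_female": np.nan, "flagged_short": True,
                }
            )
            continue
        idx = np.searchsorted(single_copy, vals)
        idx = np.minimum(idx, max(single_copy.size - 1, 0))
        is_single = single_copy.size > 0
        is_single = (single_copy[idx] == vals) if is_single else np.zeros(vals.size, bool)
        singles = vals[is_single]
        n_single = int(singles.size)
        if n_single:
            matched = female.contains_values(singles)
            pct_unmatched = 100.0 * float((~matched).sum()) / n_single
        else:
            pct_unmatched = np.nan
        rows.append(
            {
                "contig": name,
                "length": len(seq),
                "n_unique_kmers": n_unique,
                "n_single_copy": n_single,
                "pct_single_copy": 100.0 * n_single / n_unique,
                "pct_unmatched_female": pct_unmatched,
                "flagged_short": False,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coverage


def coverage_from_mapping_table(
    female, male, min_male_cov: float = 1.0
) -> pd.DataFrame:
    """Female/male coverage ratio from per-contig mean-depth tables.

    Each input is a DataFrame with columns ``contig`` and ``mean_depth``
    (or a path to such a TSV). Contigs with male depth below
    ``min_male_cov`` get an undefined-ratio flag (the quotient is noise at
    negligible male coverage).
    """
    def load(x):
        if isinstance(x, pd.DataFrame):
            return x
        return pd.read_csv(x, sep="\t")

    f, m = load(female), load(male)
    missing = set(f["contig"]).symmetric_difference(set(m["contig"]))
    if missing:
        raise ValueError(f"contigs missing from one coverage table: {sorted(missing)}")
    merged = f.merge(m, on="contig", suffixes=("_female", "_male"))
    merged = merged.rename(
        columns={"mean_depth_female": "cov_female", "mean_depth_male": "cov_male"}
    )
    defined = merged["cov_male"] >= min_male_cov
    merged["ratio_fm"] = np.where(defined, merged["cov_female"] / merged["cov_male"].where(defined, 1.0), np.nan)
    merged["ratio_defined"] = defined
    return merged[["contig", "cov_female", "cov_male", "ratio_fm", "ratio_defined"]]


# ---------------------------------------------------------------------------
# classification


@dataclass
class Thresholds:
    """Decision rule for contig classes (defaults are declared, not inferred)."""

    y_ratio_max: float = 0.3
    y_unmatched_min: float = 50.0
    x_ratio_min: float = 1.5
    x_unmatched_max: float = 25.0
    a_ratio: tuple[float, float] = (0.7, 1.3)
    min_single_copy: float = 25.0


def build_profiles(kmer_stats: pd.DataFrame, coverage: pd.DataFrame) -> pd.DataFrame:
    """Join the k-mer and coverage evidence into one profile table."""
    return kmer_stats.merge(coverage, on="contig", validate="one_to_one")


def classify_contigs(profiles: pd.DataFrame, thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Assign each contig to {Y, X, A, ambiguous}.

    Y requires a near-zero female/male ratio, a majority of single-copy
    k-mers unmatched by female reads, and enough single-copy k-mers to
    trust the signal. X requires an elevated ratio with low unmatched
    percentage; A requires a ratio near 1. Anything else is ambiguous.
    """
    t = thresholds or Thresholds()
    out = profiles.copy()
    ratio = out["ratio_fm"].to_numpy(dtype=float)
    ratio_def = out["ratio_defined"].to_numpy(dtype=bool)
    unmatched = out["pct_unmatched_female"].to_numpy(dtype=float)
    single = out["pct_single_copy"].to_numpy(dtype=float)
    eff_ratio = np.where(ratio_def, ratio, 0.0)  # undefined male floor never happens for F/M use
    is_y = (
        (eff_ratio <= t.y_ratio_max)
        & (unmatched >= t.y_unmatched_min)
        & (single >= t.min_single_copy)
    )
    is_x = (~is_y) & (eff_ratio >= t.x_ratio_min) & (unmatched <= t.x_unmatched_max)
    is_a = (~is_y) & (~is_x) & (eff_ratio >= t.a_ratio[0]) & (eff_ratio <= t.a_ratio[1])
    cls = np.full(len(out), "ambiguous", dtype=object)
    cls[is_a] = "A"
    cls[is_x] = "X"
    cls[is_y] = "Y"
    cls[np.isnan(unmatched)] = "ambiguous"
    out["assigned_class"] = cls
    out.attrs["thresholds"] = t
    return out


def class_lengths(classified: pd.DataFrame) -> pd.DataFrame:
    """Aggregate assembly bp per assigned class (sums to assembly length)."""
    agg = classified.groupby("assigned_class")["length"].sum().reset_index()
    return agg.rename(columns={"length": "total_bp"})


def write_profiles_tsv(classified: pd.DataFrame, path) -> None:
    out = classified.copy()
    t = classified.attrs.get("thresholds")
    with open(path, "w") as fh:
        if t is not None:
            fh.write(f"# thresholds: {t}\n")
        out.to_csv(fh, sep="\t", index=False)


def write_class_bed(classified: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, row in classified.iterrows():
            fh.write(f"{row['contig']}\t0\t{int(row['length'])}\t{row['assigned_class']}\n")
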