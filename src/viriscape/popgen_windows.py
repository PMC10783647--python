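"""Missing-data-aware windowed nucleotide diversity and divergence.

Diversity (pi) and absolute divergence (Dxy) are computed from per-site
allele counts that *include invariant sites*, so missing genotypes shrink
the denominator instead of being silently treated as invariant:

    pi  = sum_sites n_ref * n_alt / sum_sites C(n_called, 2)
    dxy = sum_sites (n1_ref*n2_alt + n1_alt*n2_ref) / sum_sites n1_called*n2_called

summed within fixed non-overlapping windows anchored at position 0.
Windows with no genotyped site pairs are reported as undefined (NaN),
never as zero. Samples are haploid-equivalent (inbred strains count one
allele each). Sites with more than two alleles are excluded upstream and
tallied, not estimated.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "windowed_pi",
    "windowed_dxy",
    "genome_pi",
    "genome_dxy",
    "compare_chromosome_classes",
    "read_vcf_sites",
]

_COLS = ["chrom", "pos", "allele_count_ref", "allele_count_alt", "n_called"]


def _check_sites(sites: pd.DataFrame, pop: str | None) -> pd.DataFrame:
    if pop is not None:
        if "pop" not in sites.columns:
            raise ValueError("site table has no 'pop' column")
        pops = set(sites["pop"].unique())
        if pop not in pops:
            raise ValueError(f"population {pop!r} not in table (has {sorted(pops)})")
        sites = sites[sites["pop"] == pop]
    missing = [c for c in _COLS if c not in sites.columns]
    if missing:
        raise ValueError(f"site table missing columns {missing}")
    return sites


def _window_frame(sites, window, num, den):
    w = sites["pos"].to_numpy() // window
    df = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "win": w,
            "num": num,
            "den": den,
            "used": (den > 0).astype(int),
        }
    )
    g = df.groupby(["chrom", "win"], sort=True).sum().reset_index()
    g["start"] = g["win"] * window
    g["end"] = g["start"] + window
    with np.errstate(invalid="ignore", divide="ignore"):
        g["value"] = np.where(g["den"] > 0, g["num"] / g["den"], np.nan)
    g = g.rename(columns={"num": "diff_sum", "den": "comp_sum", "used": "n_sites_used"})
    return g[["chrom", "start", "end", "value", "n_sites_used", "diff_sum", "comp_sum"]]


def windowed_pi(
    sites: pd.DataFrame,
    window: int = 20_000,
    pop: str | None = None,
) -> pd.DataFrame:
    """Nucleotide diversity in fixed windows for one population.

    Per window, pi is the ratio of summed pairwise differences to summed
    pairwise comparisons over all genotyped sites; invariant sites
    contribute to the denominator only. Sites with fewer than two called
    alleles are skipped. Returns columns chrom, start, end, pi,
    n_sites_used, diff_sum, comp_sum; empty windows carry pi = NaN.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    sites = _check_sites(sites, pop)
    nr = sites["allele_count_ref"].to_numpy(dtype=np.int64)
    na = sites["allele_count_alt"].to_numpy(dtype=np.int64)
    nc = sites["n_called"].to_numpy(dtype=np.int64)
    usable = nc >= 2
    num = np.where(usable, nr * na, 0)
    den = np.where(usable, nc * (nc - 1) // 2, 0)
    out = _window_frame(sites, window, num, den)
    return out.rename(columns={"value": "pi"})


def windowed_dxy(
    sites: pd.DataFrame,
    pop1: str,
    pop2: str,
    window: int = 20_000,
) -> pd.DataFrame:
    """Absolute divergence Dxy between two populations in fixed windows.

    Sites are joined on (chrom, pos); only sites genotyped in both
    populations contribute. Cross-population pairwise differences are
    summed and divided by the summed number of cross pairs.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if "pop" not in sites.columns:
        raise ValueError("site table has no 'pop' column")
    pops = set(sites["pop"].unique())
    for p in (pop1, pop2):
        if p not in pops:
            raise ValueError(f"population {p!r} not in table (has {sorted(pops)})")
    s1 = sites[sites["pop"] == pop1]
    s2 = sites[sites["pop"] == pop2]
    j = s1.merge(s2, on=["chrom", "pos"], suffixes=("_1", "_2"))
    n1r = j["allele_count_ref_1"].to_numpy(dtype=np.int64)
    n1a = j["allele_count_alt_1"].to_numpy(dtype=np.int64)
    n1c = j["n_called_1"].to_numpy(dtype=np.int64)
    n2r = j["allele_count_ref_2"].to_numpy(dtype=np.int64)
    n2a = j["allele_count_alt_2"].to_numpy(dtype=np.int64)
    n2c = j["n_called_2"].to_numpy(dtype=np.int64)
    usable = (n1c >= 1) & (n2c >= 1)
    num = np.where(usable, n1r * n2a + n1a * n2r, 0)
    den = np.where(usable, n1c * n2c, 0)
    frame = j[["chrom", "pos"]].copy()
    out = _window_frame(frame, window, num, den)
    return out.rename(columns={"value": "dxy"})


def genome_pi(sites: pd.DataFrame, pop: str | None = None) -> float:
    """Genome-wide pi: summed differences over summed comparisons."""
    w = windowed_pi(sites, window=2**62, pop=pop)
    d, c = w["diff_sum"].sum(), w["comp_sum"].sum()
    return float(d / c) if c > 0 else float("nan")


def genome_dxy(sites: pd.DataFrame, pop1: str, pop2: str) -> float:
    w = windowed_dxy(sites, pop1, pop2, window=2**62)
    d, c = w["diff_sum"].sum(), w["comp_sum"].sum()
    return float(d / c) if c > 0 else float("nan")


def compare_chromosome_classes(
    window_stats: pd.DataFrame,
    class_map: dict[str, str],
    value_col: str = "pi",
) -> pd.DataFrame:
    """Two-sided rank-sum tests of window statistics between chromosome classes.

    ``class_map`` assigns each chromosome to a class (e.g. A, X, fused-4).
    Every class pair with at least two defined windows each is contrasted
    with a Wilcoxon/Mann-Whitney test (ties mid-ranked, normal
    approximation with continuity correction for larger samples);
    under-filled classes are skipped with a warning.
    """
    df = window_stats.copy()
    df["class"] = df["chrom"].map(class_map)
    df = df.dropna(subset=["class", value_col])
    classes = sorted(df["class"].unique())
    rows = []
    for i, ca in enumerate(classes):
        for cb in classes[i + 1 :]:
            va = df.loc[df["class"] == ca, value_col].to_numpy()
            vb = df.loc[df["class"] == cb, value_col].to_numpy()
            if va.size < 2 or vb.size < 2:
                warnings.warn(f"contrast {ca} vs {cb} skipped (<2 windows in a class)")
                continue
            res = stats.mannwhitneyu(va, vb, alternative="two-sided", method="auto")
            rows.append(
                {
                    "class_a": ca,
                    "class_b": cb,
                    "n_a": int(va.size),
                    "n_b": int(vb.size),
                    "median_a": float(np.median(va)),
                    "median_b": float(np.median(vb)),
                    "U": float(res.statistic),
                    "p_value": float(res.pvalue),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["class_a", "class_b", "n_a", "n_b", "median_a", "median_b", "U", "p_value"],
    )


def read_vcf_sites(path, populations: dict[str, list[str]]) -> pd.DataFrame:
    """Per-site allele counts from a VCF that includes invariant sites.

    ``populations`` maps population label to sample names. Diploid
    genotypes contribute two haploid-equivalent alleles per sample;
    missing alleles reduce ``n_called``. Sites with more than two alleles
    are excluded and tallied in the returned frame's
    ``attrs['n_multiallelic']``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_idx = {s: i for i, s in enumerate(vcf.samples)}
    pop_cols = {}
    for pop, samples in populations.items():
        missing = [s for s in samples if s not in sample_idx]
        if missing:
            raise ValueError(f"samples not in VCF: {missing}")
        pop_cols[pop] = np.array([sample_idx[s] for s in samples])
    rows = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) > 1:
            n_multi += 1
            continue
        gts = np.array(var.genotype.array())[:, :-1]  # drop phasing column
        for pop, idx in pop_cols.items():
            alleles = gts[idx].ravel()
            called = alleles >= 0
            n_called = int(called.sum())
            n_alt = int((alleles[called] > 0).sum())
            rows.append(
                {
                    "chrom": var.CHROM,
                    "pos": var.POS - 1,
                    "pop": pop,
                    "allele_count_ref": n_called - n_alt,
                    "allele_count_alt": n_alt,
                    "n_called": n_called,
                }
            )
    out = pd.DataFrame(rows, columns=["chrom", "pos", "pop"] + _COLS[2:])
    out.attrs["n_multiallelic"] = n_multi
    return out
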