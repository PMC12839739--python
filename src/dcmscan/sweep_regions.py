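"""Consolidate significant SNPs into candidate sweep regions.

The region-calling chain, per chromosome:

1. group consecutive significant SNPs (q < 0.05) whose 50 kb bin indices
   differ by at most 1 (same or adjacent bins), maximally;
2. extend each group's span outward SNP by SNP, absorbing SNPs with
   q <= 0.10, stopping at the first flanking SNP with q > 0.10 (excluded)
   or the chromosome's outermost scored SNP;
3. merge regions whose intervening gap (end-exclusive,
   ``next.start - prev.end - 1``) is at most 50 kb, transitively;
4. summarize: SNP count (all scored SNPs in the span by default), the
   minimum q and its position (ties broken toward the smaller position),
   and the inclusive length ``end - start + 1``.

Gene annotation intersects regions with GTF gene intervals under the
closed-interval >= 1 bp overlap rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneRecord


@dataclass
class SweepRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # inclusive
    n_snps: int = 0
    min_q: float = math.nan
    top_snp_pos: int = 0
    gene_ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _require_sorted(df: pd.DataFrame) -> None:
    for _, grp in df.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError("SNP table must be sorted by (chrom, pos)")


def build_core_groups(snps: pd.DataFrame, sig_q: float = 0.05,
                      bin_size: int = 50_000) -> list[pd.DataFrame]:
    """Maximal runs of significant SNPs in the same or adjacent bins.

    ``snps`` needs chrom, pos, q columns sorted by (chrom, pos). The bin
    of a position is ``(pos - 1) // bin_size``; two consecutive
    significant SNPs join one group iff their bins differ by <= 1.
    """
    _require_sorted(snps)
    groups: list[pd.DataFrame] = []
    for chrom, grp in snps.groupby("chrom", sort=False):
        sig = grp[grp["q"] < sig_q]
        if sig.empty:
            continue
        bins = ((sig["pos"].to_numpy(np.int64) - 1) // bin_size)
        breaks = np.flatnonzero(np.diff(bins) > 1) + 1
        for chunk in np.split(np.arange(len(sig)), breaks):
            groups.append(sig.iloc[chunk])
    return groups


def extend_region(group: pd.DataFrame, snps: pd.DataFrame,
                  extend_q: float = 0.10) -> tuple[int, int]:
    """Extend a core group's span bidirectionally through q <= extend_q SNPs.

    Walks outward one scored SNP at a time from the group's [min pos,
    max pos]; a flanking SNP is absorbed iff its q <= ``extend_q`` (the
    threshold itself is absorbable), and the walk stops at the first SNP
    with q > ``extend_q`` or at the chromosome's outermost scored SNP.
    Returns the outermost absorbed positions.
    """
    if group.empty:
        raise ValueError("cannot extend an empty group")
    chrom = group["chrom"].iloc[0]
    chrom_snps = snps[snps["chrom"] == chrom]
    pos = chrom_snps["pos"].to_numpy(np.int64)
    q = chrom_snps["q"].to_numpy(float)
    start, end = int(group["pos"].min()), int(group["pos"].max())
    i = int(np.searchsorted(pos, start))
    j = int(np.searchsorted(pos, end))
    while i > 0 and q[i - 1] <= extend_q:
        i -= 1
    while j < pos.size - 1 and q[j + 1] <= extend_q:
        j += 1
    return int(pos[i]), int(pos[j])


def merge_regions(regions: list[SweepRegion], max_gap: int = 50_000) -> list[SweepRegion]:
    """Transitively merge same-chromosome regions separated by <= max_gap bp.

    The gap is end-exclusive: ``next.start - prev.end - 1``. Input must be
    sorted by (chrom, start) and non-overlapping within chromosomes;
    summaries of merged spans are left to ``summarize_region``.
    """
    for a, b in zip(regions, regions[1:]):
        if (a.chrom, a.start) > (b.chrom, b.start):
            raise ValueError("regions must be sorted by (chrom, start)")
        if a.chrom == b.chrom and b.start <= a.end:
            raise ValueError(f"overlapping regions on {a.chrom} at {b.start}")
    merged: list[SweepRegion] = []
    for r in regions:
        if merged and merged[-1].chrom == r.chrom and \
                r.start - merged[-1].end - 1 <= max_gap:
            merged[-1] = SweepRegion(chrom=r.chrom, start=merged[-1].start, end=r.end)
        else:
            merged.append(SweepRegion(chrom=r.chrom, start=r.start, end=r.end))
    return merged


def summarize_region(region: SweepRegion, snps: pd.DataFrame,
                     count_significant_only: bool = False,
                     sig_q: float = 0.05) -> SweepRegion:
    """Fill in SNP count, minimum q and top-SNP position for a region span.

    By default all scored SNPs inside [start, end] are counted (set
    ``count_significant_only`` to count q < sig_q SNPs instead). The top
    SNP is the minimum-q SNP; q ties go to the smallest position.
    """
    inside = snps[(snps["chrom"] == region.chrom)
                  & (snps["pos"] >= region.start) & (snps["pos"] <= region.end)]
    scored = inside[np.isfinite(inside["q"])]
    if scored.empty:
        raise ValueError(f"region {region.chrom}:{region.start}-{region.end} holds no scored SNP")
    min_q = float(scored["q"].min())
    top_pos = int(scored.loc[scored["q"] == min_q, "pos"].min())
    n = int((scored["q"] < sig_q).sum()) if count_significant_only else len(scored)
    return SweepRegion(chrom=region.chrom, start=region.start, end=region.end,
                       n_snps=n, min_q=min_q, top_snp_pos=top_pos,
                       gene_ids=list(region.gene_ids))


def build_regions(snps: pd.DataFrame, sig_q: float = 0.05, extend_q: float = 0.10,
                  bin_size: int = 50_000, merge_gap: int = 50_000,
                  count_significant_only: bool = False) -> list[SweepRegion]:
    """The full chain: group, extend, merge, summarize. Sorted output."""
    groups = build_core_groups(snps, sig_q=sig_q, bin_size=bin_size)
    spans: list[SweepRegion] = []
    for g in groups:
        start, end = extend_region(g, snps, extend_q=extend_q)
        spans.append(SweepRegion(chrom=g["chrom"].iloc[0], start=start, end=end))
    spans.sort(key=lambda r: (r.chrom, r.start))
    # extension can make neighbouring spans touch or overlap; collapse first
    collapsed: list[SweepRegion] = []
    for r in spans:
        if collapsed and collapsed[-1].chrom == r.chrom and r.start <= collapsed[-1].end:
            collapsed[-1] = SweepRegion(chrom=r.chrom, start=collapsed[-1].start,
                                        end=max(collapsed[-1].end, r.end))
        else:
            collapsed.append(r)
    merged = merge_regions(collapsed, max_gap=merge_gap)
    return [
        summarize_region(r, snps, count_significant_only=count_significant_only,
                         sig_q=sig_q)
        for r in merged
    ]


def intersect_genes(regions: list[SweepRegion],
                    genes: list[GeneRecord]) -> list[SweepRegion]:
    """Assign genes overlapping each region by >= 1 bp (closed intervals).

    Returns new regions with ``gene_ids`` filled in gene order; the
    deduplicated union across regions is available via ``gene_universe``.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for r in regions:
        hits = [g.gene_id for g in by_chrom.get(r.chrom, [])
                if g.start <= r.end and g.end >= r.start]
        out.append(SweepRegion(chrom=r.chrom, start=r.start, end=r.end,
                               n_snps=r.n_snps, min_q=r.min_q,
                               top_snp_pos=r.top_snp_pos, gene_ids=hits))
    return out


def gene_universe(regions: list[SweepRegion]) -> list[str]:
    """Deduplicated gene ids across all regions, first-seen order."""
    seen: dict[str, None] = {}
    for r in regions:
        for g in r.gene_ids:
            seen.setdefault(g, None)
    return list(seen)


def regions_frame(regions: list[SweepRegion]) -> pd.DataFrame:
    """Region table with the headline columns (chrom, span, length, counts)."""
    columns = ["chrom", "start", "end", "length", "n_snps", "min_q",
               "top_snp_pos", "gene_ids"]
    if not regions:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "length": r.length,
                "n_snps": r.n_snps,
                "min_q": r.min_q,
                "top_snp_pos": r.top_snp_pos,
                "gene_ids": ",".join(r.gene_ids),
            }
            for r in regions
        ]
    )
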