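"""Haplotype-length statistics: EHH, iHH, iHS and nSL from phased data.

Extended haplotype homozygosity (EHH) at distance d from a core site is
the probability that two random carriers of the core allele are identical
over every site from the core out to distance d. iHS integrates EHH
against physical distance for the ancestral and derived core alleles and
takes the log-ratio; nSL does the analogous comparison in segregating-site
units (the mean, over carrier pairs, of the length in sites of the maximal
interval around the core over which the pair is identical).

Polarisation: the ancestral allele is taken to be the REF allele (allele
0). This is the major polarity assumption of the module — reference
genomes are not ancestral genomes — and is why downstream tailing of
these scores defaults to absolute values. Raw scores exactly negate under
swapping the ancestral/derived labels at a core.

Defaults mirror selscan v1.3.0: EHH cutoff 0.05, core MAF 0.05, maximum
inter-SNP gap 200 kb, nSL extension cap 100 sites per side, 100
frequency bins for standardization. Cores whose EHH never falls below the
cutoff before a chromosome edge or an oversized gap are skipped rather
than integrated to a truncated endpoint.

Internally each statistic is computed from per-pair identity-run lengths:
for every unordered pair of carrier haplotypes, the number of consecutive
sites outward from the core over which the pair agrees. EHH at distance d
is then the fraction of pairs with run length >= d, and the pair-mean
shared length for nSL is the mean capped run length plus the core site.
Runs are found by chunked vectorised mismatch scans rather than
site-by-site partition refinement, which is what keeps whole-chromosome
scans fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import HaplotypeMatrix

SKIP_NONE = "none"
SKIP_MAF = "maf_below_min"
SKIP_TRUNC = "ehh_not_truncated"
SKIP_EDGE = "edge"

_CHUNK = 64  # sites per vectorised mismatch scan


@dataclass
class CoreSiteScore:
    """Per-core-SNP haplotype statistics; NaN where not computed."""

    chrom: str
    pos: int
    derived_freq: float
    ihh_derived: float = math.nan
    ihh_ancestral: float = math.nan
    ihs_raw: float = math.nan
    sl_derived: float = math.nan
    sl_ancestral: float = math.nan
    nsl_raw: float = math.nan
    ihs_std: float = math.nan
    nsl_std: float = math.nan
    skipped_reason: str = SKIP_NONE


def _carrier_rows(matrix: HaplotypeMatrix, core_index: int, allele: int) -> np.ndarray:
    return np.flatnonzero(matrix.alleles[:, core_index] == allele)


def ehh(matrix: HaplotypeMatrix, core_index: int, allele: int, direction: str,
        distance_index: int) -> float:
    """EHH among carriers of ``allele`` at ``distance_index`` sites from the core.

    Homozygosity of the partition induced by the haplotype substring from
    the core to ``core_index ± distance_index`` (inclusive); equals 1 at
    distance 0 by construction.
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    carriers = _carrier_rows(matrix, core_index, allele)
    n_c = carriers.size
    if n_c < 2:
        raise ValueError("EHH needs at least 2 carriers of the core allele")
    if distance_index == 0:
        return 1.0
    step = -1 if direction == "left" else 1
    target = core_index + step * distance_index
    if target < 0 or target >= matrix.n_sites:
        raise IndexError("distance extends past the matrix edge")
    lo, hi = sorted((core_index, target))
    segment = matrix.alleles[np.ix_(carriers, np.arange(lo, hi + 1))]
    _, inverse = np.unique(segment, axis=0, return_inverse=True)
    counts = np.bincount(inverse)
    return float((counts * (counts - 1)).sum() / (n_c * (n_c - 1)))


def _pair_run_lengths(alleles: np.ndarray, carriers: np.ndarray, core: int,
                      step: int, ehh_cutoff: float, need_sites: int
                      ) -> tuple[np.ndarray, int, bool]:
    """Identity-run length outward from the core for every carrier pair.

    Extends in chunks until the fraction of still-identical pairs falls
    below ``ehh_cutoff`` and at least ``need_sites`` sites are covered
    (or no pair survives), or the matrix edge is reached. Returns
    ``(lengths, n_sites_examined, hit_edge)``; surviving pairs carry
    length ``n_sites_examined``.
    """
    n_sites = alleles.shape[1]
    i_idx, j_idx = np.triu_indices(carriers.size, k=1)
    total = i_idx.size
    lengths = np.zeros(total, dtype=np.int64)
    active = np.arange(total)
    sub = alleles[carriers]
    dist = 0
    while active.size:
        if step > 0:
            lo = core + dist + 1
            if lo > n_sites - 1:
                break
            cols = np.arange(lo, min(lo + _CHUNK, n_sites))
        else:
            hi = core - dist - 1
            if hi < 0:
                break
            cols = np.arange(hi, max(hi - _CHUNK, -1), -1)
        block = sub[:, cols]
        mism = block[i_idx[active]] != block[j_idx[active]]
        any_mis = mism.any(axis=1)
        first = np.where(any_mis, mism.argmax(axis=1), cols.size)
        lengths[active] += first
        active = active[~any_mis]
        dist += cols.size
        if active.size / total < ehh_cutoff and dist >= need_sites:
            break
    if step > 0:
        hit_edge = core + dist >= n_sites - 1
    else:
        hit_edge = core - dist <= 0
    return lengths, dist, hit_edge


def _ehh_curve(lengths: np.ndarray, dist: int) -> np.ndarray:
    """EHH at distances 1..dist from per-pair run lengths."""
    total = lengths.size
    counts = np.bincount(np.minimum(lengths, dist), minlength=dist + 1)
    ge = np.cumsum(counts[::-1])[::-1]  # ge[d] = #pairs with length >= d
    return ge[1:] / total


def _ihh_side(matrix: HaplotypeMatrix, carriers: np.ndarray, core: int,
              step: int, ehh_cutoff: float, max_gap_bp: int) -> tuple[float, bool]:
    lengths, dist, hit_edge = _pair_run_lengths(
        matrix.alleles, carriers, core, step, ehh_cutoff, need_sites=0)
    if dist == 0:
        return 0.0, False  # core at the matrix edge
    curve = _ehh_curve(lengths, dist)
    below = np.flatnonzero(curve < ehh_cutoff)
    pos = matrix.positions
    idx = core + step * np.arange(1, dist + 1)
    x = pos[idx].astype(np.int64)
    gaps = np.abs(np.diff(x, prepend=pos[core]))
    if below.size == 0:
        # EHH never dropped below the cutoff before the edge
        return math.nan, False
    d_star = below[0]  # index of the first sub-cutoff site
    big_gap = np.flatnonzero(gaps[: d_star + 1] > max_gap_bp)
    if big_gap.size:
        return math.nan, False
    y = np.concatenate(([1.0], curve[: d_star + 1]))
    xx = np.concatenate(([pos[core]], x[: d_star + 1])).astype(float)
    area = float(np.sum(0.5 * (y[1:] + y[:-1]) * np.abs(np.diff(xx))))
    return area, True


def ihh(matrix: HaplotypeMatrix, core_index: int, allele: int,
        ehh_cutoff: float = 0.05, max_gap_bp: int = 200_000) -> tuple[float, bool]:
    """Integrated EHH (trapezoids over physical bp), both sides summed.

    Each side extends site by site until EHH drops below ``ehh_cutoff``;
    the trapezoid ending at the first sub-cutoff site is included. Returns
    ``(area, truncated_ok)`` where ``truncated_ok`` is False when a
    chromosome edge or an inter-SNP gap larger than ``max_gap_bp`` is hit
    before the cutoff on either side; such cores should be skipped by the
    caller, matching selscan's default (no --trunc-ok).
    """
    carriers = _carrier_rows(matrix, core_index, allele)
    if carriers.size < 2:
        raise ValueError("iHH needs at least 2 carriers of the core allele")
    area = 0.0
    truncated_ok = True
    for step in (-1, 1):
        side_area, ok = _ihh_side(matrix, carriers, core_index, step,
                                  ehh_cutoff, max_gap_bp)
        if ok:
            area += side_area
        else:
            truncated_ok = False
    return area, truncated_ok


def _sl_mean(matrix: HaplotypeMatrix, carriers: np.ndarray, core: int,
             max_extend_sites: int) -> float:
    """Mean over carrier pairs of the shared-interval length in sites.

    Per pair this is 1 (the core) plus the identity-run length on each
    side, each side capped at ``max_extend_sites``.
    """
    total = carriers.size * (carriers.size - 1) / 2.0
    acc = 0.0
    for step in (-1, 1):
        # cutoff 2.0 never binds: extension stops at the site cap or edge
        lengths, _dist, _edge = _pair_run_lengths(
            matrix.alleles, carriers, core, step,
            ehh_cutoff=2.0, need_sites=max_extend_sites)
        acc += float(np.minimum(lengths, max_extend_sites).sum())
    return 1.0 + acc / total


def ihs_scan(matrix: HaplotypeMatrix, min_maf: float = 0.05,
             ehh_cutoff: float = 0.05, max_gap_bp: int = 200_000) -> list[CoreSiteScore]:
    """Unstandardized iHS at every eligible core SNP.

    ``ihs_raw = ln(iHH_ancestral / iHH_derived)``: negative values mean
    unusually long haplotypes around the derived (ALT) allele. Cores with
    MAF below ``min_maf`` (or fewer than two carriers of either allele)
    and cores whose EHH cannot be integrated to the cutoff are skipped
    with a reason rather than scored.
    """
    n = matrix.n_haplotypes
    out: list[CoreSiteScore] = []
    alt_counts = matrix.alleles.sum(axis=0).astype(np.int64)
    for k in range(matrix.n_sites):
        j = int(alt_counts[k])
        freq = j / n
        score = CoreSiteScore(chrom=matrix.chrom, pos=int(matrix.positions[k]),
                              derived_freq=freq)
        if min(freq, 1.0 - freq) < min_maf or j < 2 or n - j < 2:
            score.skipped_reason = SKIP_MAF
        elif k == 0 or k == matrix.n_sites - 1:
            score.skipped_reason = SKIP_EDGE
        else:
            ihh_d, ok_d = ihh(matrix, k, 1, ehh_cutoff, max_gap_bp)
            ihh_a, ok_a = ihh(matrix, k, 0, ehh_cutoff, max_gap_bp)
            score.ihh_derived, score.ihh_ancestral = ihh_d, ihh_a
            if not (ok_d and ok_a):
                score.skipped_reason = SKIP_TRUNC
            elif ihh_d > 0 and ihh_a > 0:
                score.ihs_raw = math.log(ihh_a / ihh_d)
            else:
                score.skipped_reason = SKIP_TRUNC
        out.append(score)
    return out


def nsl_scan(matrix: HaplotypeMatrix, min_maf: float = 0.05,
             max_extend_sites: int = 100) -> list[CoreSiteScore]:
    """Unstandardized nSL at every eligible core SNP.

    ``nsl_raw = ln(SL_ancestral / SL_derived)`` with SL the mean pairwise
    shared-interval length in sites (capped per side). SL >= 1 always (the
    core site itself), so the ratio is well defined at every kept core.
    """
    n = matrix.n_haplotypes
    out: list[CoreSiteScore] = []
    alt_counts = matrix.alleles.sum(axis=0).astype(np.int64)
    for k in range(matrix.n_sites):
        j = int(alt_counts[k])
        freq = j / n
        score = CoreSiteScore(chrom=matrix.chrom, pos=int(matrix.positions[k]),
                              derived_freq=freq)
        if min(freq, 1.0 - freq) < min_maf or j < 2 or n - j < 2:
            score.skipped_reason = SKIP_MAF
        else:
            der = _carrier_rows(matrix, k, 1)
            anc = _carrier_rows(matrix, k, 0)
            sl_d = _sl_mean(matrix, der, k, max_extend_sites)
            sl_a = _sl_mean(matrix, anc, k, max_extend_sites)
            score.sl_derived, score.sl_ancestral = sl_d, sl_a
            score.nsl_raw = math.log(sl_a / sl_d)
        out.append(score)
    return out


def standardize_by_freq_bins(scores: list[CoreSiteScore], stat: str,
                             n_bins: int = 100, min_per_bin: int = 20) -> list[CoreSiteScore]:
    """Z-standardize raw scores within derived-allele-frequency bins.

    Grouping is per chromosome. Equal-width bins over [0, 1]; adjacent
    bins are merged left-to-right until each effective bin holds at least
    ``min_per_bin`` scored cores (a short trailing bin merges backward).
    The population standard deviation (divide by n) is the frozen
    convention; zero-variance bins leave their scores missing.

    Mutates and returns ``scores``.
    """
    if stat not in ("ihs", "nsl"):
        raise ValueError("stat must be 'ihs' or 'nsl'")
    raw_attr = f"{stat}_raw"
    std_attr = f"{stat}_std"

    by_chrom: dict[str, list[CoreSiteScore]] = {}
    for s in scores:
        by_chrom.setdefault(s.chrom, []).append(s)

    for chrom_scores in by_chrom.values():
        usable = [s for s in chrom_scores if not math.isnan(getattr(s, raw_attr))]
        if not usable:
            continue
        bin_of = {
            id(s): min(int(s.derived_freq * n_bins), n_bins - 1) for s in usable
        }
        counts = np.bincount([bin_of[id(s)] for s in usable], minlength=n_bins)
        # greedy left-to-right merge into effective bins of >= min_per_bin
        group_of_bin = np.empty(n_bins, dtype=np.int64)
        group, acc = 0, 0
        for b in range(n_bins):
            group_of_bin[b] = group
            acc += counts[b]
            if acc >= min_per_bin:
                group += 1
                acc = 0
        if acc > 0 and group > 0:  # trailing underfull group merges backward
            group_of_bin[group_of_bin == group] = group - 1
        groups: dict[int, list[CoreSiteScore]] = {}
        for s in usable:
            groups.setdefault(int(group_of_bin[bin_of[id(s)]]), []).append(s)
        for members in groups.values():
            vals = np.array([getattr(s, raw_attr) for s in members])
            mu = float(vals.mean())
            sd = float(vals.std())  # population sd, frozen convention
            if sd == 0.0:
                continue  # zero variance: leave std missing
            for s in members:
                setattr(s, std_attr, (getattr(s, raw_attr) - mu) / sd)
    return scores


def scores_frame(scores: list[CoreSiteScore], stat: str) -> pd.DataFrame:
    """selscan-style output columns for cross-checking against tool files."""
    if stat == "ihs":
        rows = [
            {"id": f"{s.chrom}:{s.pos}", "pos": s.pos, "freq": s.derived_freq,
             "ihh1": s.ihh_derived, "ihh0": s.ihh_ancestral,
             "unstandardized": s.ihs_raw, "standardized": s.ihs_std,
             "skipped_reason": s.skipped_reason}
            for s in scores
        ]
    elif stat == "nsl":
        rows = [
            {"id": f"{s.chrom}:{s.pos}", "pos": s.pos, "freq": s.derived_freq,
             "sl1": s.sl_derived, "sl0": s.sl_ancestral,
             "unstandardized": s.nsl_raw, "standardized": s.nsl_std,
             "skipped_reason": s.skipped_reason}
            for s in scores
        ]
    else:
        raise ValueError("stat must be 'ihs' or 'nsl'")
    return pd.DataFrame(rows)
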