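"""Site-frequency-spectrum statistics: windowed pi and Tajima's D.

Nucleotide diversity pi and Tajima's D are computed in non-overlapping
windows (default 50 kb) anchored at position 1: window k covers
``[(k-1)*W + 1, k*W]`` in 1-based inclusive coordinates. Per-window
values are then copied onto every SNP inside the window so SNP-level
composite scoring can use them.

Conventions (frozen; see the methods note):

* the windowed-pi denominator is the full window span ``W`` even in the
  last, partially covered window (VCFtools ``--window-pi`` behaviour),
  configurable to the covered span;
* windows containing no SNP are omitted from the output;
* Tajima's D is reported missing (NaN), not zero, when a window holds
  fewer than two segregating sites — its variance term degenerates;
* ``pi_hat`` entering D is the TOTAL mean pairwise difference count in
  the window (sum of per-site heterozygosities), not the per-bp pi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import HaplotypeMatrix


@dataclass
class Window:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # inclusive, start + window_size - 1
    n_snps: int
    pi: float  # per-bp diversity
    tajimas_d: float  # NaN when fewer than 2 segregating sites


def per_site_pi(alt_count: int, n_haplotypes: int) -> float:
    """Heterozygosity of one site: expected pairwise difference.

    Equals ``2 j (n - j) / (n (n - 1))`` for ``j`` alternate alleles among
    ``n`` haplotypes — the fraction of unordered haplotype pairs that
    differ at the site.
    """
    n, j = n_haplotypes, alt_count
    if n < 2:
        raise ValueError("per-site pi needs at least 2 haplotypes")
    if not 0 <= j <= n:
        raise ValueError(f"alt count {j} outside [0, {n}]")
    return 2.0 * j * (n - j) / (n * (n - 1.0))


def tajimas_d(S: int, pi_hat: float, n: int) -> float:
    """Tajima's D from segregating-site count and total mean pairwise diversity.

    ``pi_hat`` is the mean number of pairwise differences over the whole
    window (total, not per-bp). Returns NaN when ``S < 2``: the variance
    normalisation is degenerate there.
    """
    if S < 0:
        raise ValueError("S must be non-negative")
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 haplotypes")
    if S < 2:
        return math.nan
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1.0))


def windowed_pi(
    matrix: HaplotypeMatrix,
    window_size: int = 50_000,
    span_denominator: str = "window",
) -> list[Window]:
    """Per-window pi (per bp) and Tajima's D over non-overlapping windows.

    Parameters
    ----------
    window_size : window span W in bp; window k is [(k-1)W+1, kW].
    span_denominator : "window" divides the summed site heterozygosity by
        W (VCFtools convention); "covered" divides by the span actually
        inside the chromosome for the trailing window.
    """
    if span_denominator not in ("window", "covered"):
        raise ValueError("span_denominator must be 'window' or 'covered'")
    n = matrix.n_haplotypes
    if matrix.n_sites == 0:
        return []
    alt_counts = matrix.alleles.sum(axis=0).astype(np.int64)
    het = 2.0 * alt_counts * (n - alt_counts) / (n * (n - 1.0))
    segregating = (alt_counts > 0) & (alt_counts < n)

    win_index = (matrix.positions - 1) // window_size
    out: list[Window] = []
    chrom_end = int(matrix.positions[-1])
    for k in np.unique(win_index):
        mask = win_index == k
        if not mask.any():
            continue
        seg_mask = mask & segregating
        S = int(seg_mask.sum())
        if S == 0:
            continue  # no polymorphic site: window omitted
        start = int(k) * window_size + 1
        end = start + window_size - 1
        pi_total = float(het[mask].sum())
        if span_denominator == "window":
            span = window_size
        else:
            span = min(end, chrom_end) - start + 1
        out.append(
            Window(
                chrom=matrix.chrom,
                start=start,
                end=end,
                n_snps=int(mask.sum()),
                pi=pi_total / span,
                tajimas_d=tajimas_d(S, pi_total, n) if n >= 4 else math.nan,
            )
        )
    return out


def assign_window_values_to_snps(
    windows: list[Window], positions: np.ndarray, chrom: str | None = None
) -> pd.DataFrame:
    """Copy each window's (pi, D) onto the SNPs falling inside it.

    Raises if any SNP lies outside every computed window — that indicates
    a window bookkeeping bug, since windows are derived from the same SNP
    set.
    """
    positions = np.asarray(positions, dtype=np.int64)
    pi_col = np.full(positions.size, np.nan)
    d_col = np.full(positions.size, np.nan)
    assigned = np.zeros(positions.size, dtype=bool)
    for w in windows:
        if chrom is not None and w.chrom != chrom:
            continue
        mask = (positions >= w.start) & (positions <= w.end)
        pi_col[mask] = w.pi
        d_col[mask] = w.tajimas_d
        assigned |= mask
    if not assigned.all():
        missing = positions[~assigned][:5]
        raise ValueError(f"SNPs outside every window (first few: {missing.tolist()})")
    return pd.DataFrame({"pos": positions, "pi": pi_col, "tajimas_d": d_col})


def windows_frame(windows: list[Window]) -> pd.DataFrame:
    """Windows as a TSV-ready frame (chrom, start, end, n_snps, pi, tajimas_d)."""
    return pd.DataFrame(
        [
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "n_snps": w.n_snps,
                "pi": w.pi,
                "tajimas_d": w.tajimas_d,
            }
            for w in windows
        ]
    )
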