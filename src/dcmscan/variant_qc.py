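"""Site- and sample-level filters defining the analysis-ready SNP set.

Two stages mirror a standard short-read germline workflow:

1. Hard filters on per-site annotations (GATK-style QD/FS/SOR/MQ rank-sum
   thresholds plus site depth and QUAL). A rule whose INFO field is absent
   does not fire — absent annotations are tolerated and logged, never
   treated as failures.
2. PLINK-style call-rate and minor-allele-frequency filtering on the
   genotype table, in the fixed order: samples by call rate, then sites by
   call rate on the remaining samples, then sites by MAF on the remaining
   samples. All inequalities are strict, exactly as printed tool defaults:
   call rates must exceed 0.9 and MAF must exceed 0.05 to survive.

MAF is computed from allele counts over non-missing alleles (PLINK
convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import VariantSite


@dataclass(frozen=True)
class QcThresholds:
    min_depth: int = 10
    max_depth: int = 500
    min_qual: float = 30.0
    max_qd_low: float = 2.0  # reject QD < 2.0
    max_fs: float = 60.0  # reject FS > 60.0
    max_sor: float = 4.0  # reject SOR > 4.0
    min_mq: float = 40.0  # reject MQ < 40.0
    min_mqranksum: float = -12.5  # reject MQRankSum < -12.5
    min_readposranksum: float = -8.0  # reject ReadPosRankSum < -8.0
    min_sample_call_rate: float = 0.9
    min_snp_call_rate: float = 0.9
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_sample_call_rate", "min_snp_call_rate", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_depth >= self.max_depth:
            raise ValueError("min_depth must be < max_depth")


def _hard_filter_rules(t: QcThresholds):
    # (rule name, INFO key or special, predicate returning True when the rule FIRES)
    return [
        ("DP_low", "DP", lambda v: v < t.min_depth),
        ("DP_high", "DP", lambda v: v > t.max_depth),
        ("QUAL_low", "QUAL", lambda v: v < t.min_qual),
        ("QD_low", "QD", lambda v: v < t.max_qd_low),
        ("FS_high", "FS", lambda v: v > t.max_fs),
        ("SOR_high", "SOR", lambda v: v > t.max_sor),
        ("MQ_low", "MQ", lambda v: v < t.min_mq),
        ("MQRankSum_low", "MQRankSum", lambda v: v < t.min_mqranksum),
        ("ReadPosRankSum_low", "ReadPosRankSum", lambda v: v < t.min_readposranksum),
    ]


def apply_hard_filters(
    sites: list[VariantSite], thresholds: QcThresholds | None = None
) -> tuple[list[VariantSite], dict[str, int]]:
    """Remove sites failing any hard-filter rule.

    A site is removed if ANY rule fires. Every firing rule is attributed in
    the returned counts (a site failing two rules increments both), plus a
    ``missing_field`` count of rule evaluations skipped because the INFO
    annotation was absent, and a ``removed`` total.
    """
    t = thresholds or QcThresholds()
    rules = _hard_filter_rules(t)
    counts = {name: 0 for name, _, _ in rules}
    counts["missing_field"] = 0
    counts["removed"] = 0
    kept = []
    for site in sites:
        failed = False
        for name, key, fires in rules:
            value = site.qual if key == "QUAL" else site.info_fields.get(key)
            if value is None:
                counts["missing_field"] += 1
                continue
            if fires(value):
                counts[name] += 1
                failed = True
        if failed:
            counts["removed"] += 1
        else:
            kept.append(site)
    return kept, counts


def filter_call_rate_and_maf(
    genotypes: pd.DataFrame, thresholds: QcThresholds | None = None
) -> tuple[list, list]:
    """PLINK-style sample/site call-rate and MAF filtering.

    ``genotypes`` is samples x sites with entries in {0, 1, 2, NaN}
    (alternate-allele dosage per diploid sample, NaN = missing call).

    Order is fixed: samples first, then site call rate, then MAF, each
    recomputed on the survivors of the previous step. Returns the kept
    sample index and kept site (column) labels.
    """
    t = thresholds or QcThresholds()
    g = genotypes.to_numpy(dtype=float)
    if g.size == 0:
        raise ValueError("empty genotype table")

    called = ~np.isnan(g)
    sample_rate = called.mean(axis=1)
    keep_samples = sample_rate > t.min_sample_call_rate
    if not keep_samples.any():
        raise ValueError(
            "no sample passes the call-rate threshold; review QC thresholds"
        )

    g2 = g[keep_samples]
    called2 = ~np.isnan(g2)
    site_rate = called2.mean(axis=0)
    keep_sites = site_rate > t.min_snp_call_rate

    # MAF over non-missing alleles of remaining samples
    alt = np.nansum(g2, axis=0)
    total = 2.0 * called2.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
    maf = np.minimum(p, 1.0 - p)
    keep_sites = keep_sites & (maf > t.min_maf)

    if not keep_sites.any():
        raise ValueError("no site passes call-rate/MAF thresholds; review QC thresholds")

    kept_samples = list(genotypes.index[keep_samples])
    kept_sites = list(genotypes.columns[keep_sites])
    return kept_samples, kept_sites


def filter_matrix_maf(matrix, min_maf: float = 0.05):
    """Drop sites with MAF <= min_maf from a complete phased matrix.

    The strict inequality matches the PLINK-style "MAF > 0.05" filter that
    defines the analysis-ready SNP set; every downstream statistic (window
    diversity, Tajima's D, iHS, nSL) is computed on the filtered set.
    Returns (filtered matrix, number of sites removed).
    """
    from .io_formats import HaplotypeMatrix

    n = matrix.n_haplotypes
    freq = matrix.alleles.sum(axis=0) / n
    keep = np.minimum(freq, 1.0 - freq) > min_maf
    removed = int((~keep).sum())
    if removed == 0:
        return matrix, 0
    return (
        HaplotypeMatrix(
            chrom=matrix.chrom,
            positions=matrix.positions[keep],
            alleles=matrix.alleles[:, keep],
            sample_ids=matrix.sample_ids,
        ),
        removed,
    )


def qc_report_frame(counts: dict[str, int]) -> pd.DataFrame:
    """Hard-filter rejection counts as a two-column TSV-ready frame."""
    return pd.DataFrame(
        {"rule": list(counts.keys()), "count": list(counts.values())}
    )
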