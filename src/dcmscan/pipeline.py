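"""Orchestration: QC -> windowed stats -> haplotype stats -> DCMS -> regions.

``run_scan`` takes one declarative configuration and writes every stage
output (windows, per-SNP scores, regions, BED, genes) plus a JSON run
log recording thresholds, seeds, library versions, per-stage counts and
output checksums — the log alone suffices to reproduce a run, and
re-running an identical configuration reproduces byte-identical score
tables.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dcms_core import DEFAULT_MCD_SEED, score_table
from .haplo_stats import ihs_scan, nsl_scan, scores_frame, standardize_by_freq_bins
from .io_formats import read_gtf_genes, read_phased_vcf, write_regions_bed
from .sfs_stats import assign_window_values_to_snps, windowed_pi, windows_frame
from .sweep_regions import build_regions, gene_universe, intersect_genes, regions_frame
from .variant_qc import filter_matrix_maf


@dataclass
class PipelineConfig:
    vcf_path: str
    out_dir: str
    gtf_path: str | None = None
    chrom_filter: str | None = None
    window_size: int = 50_000
    bin_size: int = 50_000
    sig_q: float = 0.05
    extend_q: float = 0.10
    merge_gap: int = 50_000
    min_maf: float = 0.05
    ehh_cutoff: float = 0.05
    max_gap_bp: int = 200_000
    nsl_max_extend: int = 100
    std_bins: int = 100
    std_min_per_bin: int = 20
    mcd_alpha: float = 0.75
    mcd_nsamp: int = 50_000
    mcd_seed: int = DEFAULT_MCD_SEED
    signed_tails: bool = False
    max_missing_stats: int = 1
    fdr_method: str = "storey"
    count_significant_only: bool = False

    def __post_init__(self) -> None:
        for name in ("sig_q", "extend_q", "min_maf", "ehh_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0.5 <= self.mcd_alpha <= 1.0:
            raise ValueError("mcd_alpha must be in [0.5, 1]")
        if self.window_size <= 0 or self.bin_size <= 0 or self.merge_gap < 0:
            raise ValueError("window_size/bin_size must be positive, merge_gap >= 0")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def snp_statistics(matrices: dict, config: PipelineConfig) -> tuple[pd.DataFrame, list]:
    """Per-SNP harmonized statistics for all chromosomes (pre-DCMS)."""
    all_windows = []
    frames = []
    for chrom in sorted(matrices):
        mat = matrices[chrom]
        windows = windowed_pi(mat, window_size=config.window_size)
        all_windows.extend(windows)
        wcols = assign_window_values_to_snps(windows, mat.positions, chrom=chrom)
        ihs = standardize_by_freq_bins(
            ihs_scan(mat, min_maf=config.min_maf, ehh_cutoff=config.ehh_cutoff,
                     max_gap_bp=config.max_gap_bp),
            "ihs", n_bins=config.std_bins, min_per_bin=config.std_min_per_bin)
        nsl = standardize_by_freq_bins(
            nsl_scan(mat, min_maf=config.min_maf,
                     max_extend_sites=config.nsl_max_extend),
            "nsl", n_bins=config.std_bins, min_per_bin=config.std_min_per_bin)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": mat.positions,
            "pi": wcols["pi"].to_numpy(),
            "tajimas_d": wcols["tajimas_d"].to_numpy(),
            "ihs_std": [s.ihs_std for s in ihs],
            "nsl_std": [s.nsl_std for s in nsl],
        }))
    return pd.concat(frames, ignore_index=True), all_windows


def run_scan(config: PipelineConfig) -> dict:
    """Run the full scan; returns a result bundle of paths and tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__ as pkg_version

    log: dict = {
        "dcmscan_version": pkg_version,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": asdict(config),
        "stages": {},
    }

    matrices, sites, skipped = read_phased_vcf(config.vcf_path, config.chrom_filter)
    if not matrices:
        raise ValueError("no biallelic phased SNPs read from the VCF")
    n_snps_in = sum(m.n_sites for m in matrices.values())
    log["stages"]["read_vcf"] = {"snps": n_snps_in, "skipped": skipped,
                                 "chromosomes": sorted(matrices)}

    # the MAF filter defines the analysis-ready SNP set: every statistic
    # downstream (window diversity, D, iHS, nSL) sees only MAF > min_maf
    maf_removed = 0
    for chrom in list(matrices):
        matrices[chrom], removed = filter_matrix_maf(matrices[chrom],
                                                     config.min_maf)
        maf_removed += removed
    log["stages"]["maf_filter"] = {
        "removed": maf_removed,
        "snps": sum(m.n_sites for m in matrices.values()),
    }

    snp_stats, windows = snp_statistics(matrices, config)
    log["stages"]["statistics"] = {
        "windows": len(windows),
        "snps": len(snp_stats),
        "ihs_scored": int(np.isfinite(snp_stats["ihs_std"]).sum()),
        "nsl_scored": int(np.isfinite(snp_stats["nsl_std"]).sum()),
    }

    scored, model, mu, sigma = score_table(
        snp_stats, mcd_alpha=config.mcd_alpha, mcd_nsamp=config.mcd_nsamp,
        mcd_seed=config.mcd_seed, signed_tails=config.signed_tails,
        max_missing=config.max_missing_stats, fdr_method=config.fdr_method)
    log["stages"]["dcms"] = {
        "mu": mu, "sigma": sigma,
        "correlation": model.matrix.tolist(),
        "weights": model.column_weights.tolist(),
        "snps_scored": int(np.isfinite(scored["dcms"]).sum()),
        "significant": int((scored["q"] < config.sig_q).sum()),
    }

    scored_only = scored[np.isfinite(scored["q"])].reset_index(drop=True)
    regions = build_regions(
        scored_only, sig_q=config.sig_q, extend_q=config.extend_q,
        bin_size=config.bin_size, merge_gap=config.merge_gap,
        count_significant_only=config.count_significant_only)
    genes = []
    if config.gtf_path:
        genes = read_gtf_genes(config.gtf_path)
        regions = intersect_genes(regions, genes)
    log["stages"]["regions"] = {
        "regions": len(regions),
        "unique_genes": len(gene_universe(regions)),
    }

    paths = {
        "windows": out / "windows.tsv",
        "snp_scores": out / "snp_scores.tsv",
        "regions": out / "regions.tsv",
        "bed": out / "regions.bed",
        "genes": out / "region_genes.tsv",
        "gene_universe": out / "gene_universe.txt",
        "log": out / "run_log.json",
        "config": out / "config.yaml",
    }
    _write_tsv(windows_frame(windows), paths["windows"])
    _write_tsv(scored, paths["snp_scores"])
    _write_tsv(regions_frame(regions), paths["regions"])
    write_regions_bed(regions, str(paths["bed"]))
    _write_tsv(
        pd.DataFrame(
            [{"chrom": r.chrom, "start": r.start, "end": r.end,
              "gene_ids": ",".join(r.gene_ids)} for r in regions],
            columns=["chrom", "start", "end", "gene_ids"],
        ),
        paths["genes"],
    )
    paths["gene_universe"].write_text(
        "".join(f"{g}\n" for g in gene_universe(regions)))
    config.to_yaml(str(paths["config"]))

    log["checksums"] = {
        name: _sha256(p) for name, p in paths.items() if name not in ("log",)
    }
    paths["log"].write_text(json.dumps(log, indent=2, sort_keys=True))

    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "snp_scores": scored,
        "windows": windows,
        "regions": regions,
        "model": model,
        "mu": mu,
        "sigma": sigma,
        "log": log,
    }


def manhattan_plot(snp_scores: pd.DataFrame | str, out_path: str,
                   sig_q: float = 0.05) -> None:
    """-log10(q) against position, coloured by chromosome (cosmetic only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(snp_scores, str):
        snp_scores = pd.read_csv(snp_scores, sep="\t")
    if "q" not in snp_scores.columns:
        raise ValueError("score table lacks a q column")
    fig, ax = plt.subplots(figsize=(10, 3.5))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(snp_scores.groupby("chrom", sort=True)):
        x = grp["pos"].to_numpy(float) + offset
        with np.errstate(divide="ignore"):
            y = -np.log10(grp["q"].to_numpy(float))
        ax.scatter(x, y, s=4, color=f"C{i % 10}", linewidths=0)
        ticks.append(offset + grp["pos"].max() / 2)
        labels.append(str(chrom))
        offset += grp["pos"].max()
    ax.axhline(-math.log10(sig_q), color="grey", ls="--", lw=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(q)$")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
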