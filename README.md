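# dcmscan

Within-population selective-sweep scanning from phased SNP data.

`dcmscan` is for population geneticists who have a phased, biallelic SNP
call set for a single population — typically a livestock breed or other
small managed population resequenced at modest sample size — and want to
locate genomic regions showing the joint signature of a selective sweep:
depressed nucleotide diversity, a skewed site-frequency spectrum, and
extended haplotype homozygosity.

## The method

Four intra-population statistics are computed per SNP:

* **π** (nucleotide diversity) and **Tajima's D** in non-overlapping
  50 kb windows, each window's value assigned to the SNPs inside it;
* **iHS** (integrated haplotype score) and **nSL** (number of
  segregating sites by length) from the phased haplotypes, standardized
  within derived-allele-frequency bins per chromosome.

Each statistic becomes a one-tailed empirical p-value by genome-wide
ranking (left-tailed for π and D, right-tailed for |iHS| and |nSL|),
and the four are combined into the de-correlated composite

```
DCMS_l = Σ_t  logit(1 − p_lt) / w_t ,    w_t = Σ_s |r_st| ,
```

where `r` is the statistic-by-statistic correlation matrix estimated
robustly with the Minimum Covariance Determinant (α = 0.75), so that
statistics carrying redundant information are down-weighted. The
composite is calibrated against a robust (Huber) normal fit to give
right-tailed p-values, Storey q-values control the FDR, and SNPs with
q < 0.05 are consolidated into sweep regions by 50 kb binning,
bidirectional extension through q ≤ 0.10 flanks, and merging of regions
≤ 50 kb apart. Regions are intersected with GTF gene annotation.

A forward Wright–Fisher simulator (neutral background plus optional
hard sweep with known position and selection coefficient) generates
fully synthetic phased VCFs, so every stage is testable without any
download. See `docs/methods.md` for model details, conventions and
limitations.

## Worked example

Simulate a 2 Mb chromosome carrying a hard sweep (s = 0.05 driven to
allele frequency ≥ 0.8 at position 1,025,000), scan it together with
two neutral chromosomes, and annotate against a toy GTF:

```bash
dcmscan simulate --out-vcf bg1.vcf --seed 11
dcmscan simulate --out-vcf bg2.vcf --seed 12
dcmscan simulate --out-vcf sweep.vcf --seed 13 --s 0.05 \
        --sweep-pos 1025000 --truth-json truth.json
# merge the three chromosomes into one VCF with your favourite tool, or
# drive everything from Python:
```

```python
from dcmscan import (SimulationConfig, simulate_population,
                     write_phased_vcf, PipelineConfig, run_scan)

mats = {}
for chrom, (seed, s) in {"1": (11, 0.0), "2": (12, 0.0), "3": (13, 0.05)}.items():
    mats[chrom], truth = simulate_population(
        SimulationConfig(seed=seed, s=s, chrom=chrom))
write_phased_vcf(mats, "genome.vcf")

res = run_scan(PipelineConfig(vcf_path="genome.vcf", out_dir="scan_out"))
print(res["log"]["stages"]["dcms"]["significant"], "significant SNPs")
for r in res["regions"]:
    print(r.chrom, r.start, r.end, r.length, r.n_snps, f"{r.min_q:.2e}")
```

With the seeds above this prints

```
3 significant SNPs
2 1054195 1054195 1 1 4.64e-04
3 406404 426354 19951 3 1.82e-02
```

— the columns are chromosome, start, end, inclusive length, scored-SNP
count and minimum q. Two candidate regions survive q < 0.05: a
single-SNP region on neutral chromosome 2 and a ~20 kb region on the
sweep chromosome. Purely neutral genomes typically print
`0 significant SNPs` and an empty region table. At this deliberately
small scale (≈ 1,000 SNPs per 2 Mb chromosome, 30 haplotypes) the
composite's extreme tail is noisy and candidate regions do not reliably
pin the planted sweep position — `docs/methods.md` quantifies why — so
treat single-replicate regions as candidates, exactly as one would with
real data. `scan_out/` holds the window table, the per-SNP score table
(statistics, one-tailed p-values, DCMS, calibrated p, q), the region
table, a BED export, gene assignments and a JSON run log with every
threshold, seed and output checksum; re-running the same configuration
reproduces the outputs byte for byte.

The CLI mirrors the library: `simulate`, `qc`, `stats`, `dcms`,
`regions`, `annotate`, `run-all`, `plot` (Manhattan plot of −log10 q).

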