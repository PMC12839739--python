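# Methods

`dcmscan` detects within-population selective sweeps from phased biallelic
SNPs by combining four intra-population statistics into the DCMS
composite, calibrating it to p- and q-values, and consolidating
significant SNPs into candidate regions. This note records the models,
conventions, parameter choices and known limitations.

## The scan

### Windowed site-frequency statistics

Nucleotide diversity π and Tajima's D are computed in non-overlapping
windows of W = 50,000 bp anchored at position 1 (window k covers
`[(k−1)W+1, kW]`, 1-based inclusive). Per site with derived count j among
n haplotypes, heterozygosity is `2j(n−j)/(n(n−1))`; windowed π divides
the summed site heterozygosity by the full window span W (VCFtools
`--window-pi` convention; a "covered span" option exists for the trailing
window). Tajima's D uses the standard a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂
normalisation with the *total* mean pairwise difference count per window.
D is reported missing (not zero) when a window has fewer than two
segregating sites, because its variance term degenerates. SNP-less
windows are omitted. Window values are copied onto every SNP inside the
window so that all four statistics live at SNP resolution.

### Haplotype statistics

EHH at distance d from a core site is the probability that two random
carriers of the core allele are identical at every site from the core out
to d. iHH integrates EHH against physical distance with trapezoids,
extending each side until EHH < 0.05; the trapezoid ending at the first
sub-cutoff site is included. A core is skipped (not scored) when a
chromosome edge or an inter-SNP gap above 200 kb is reached before the
cutoff, matching selscan v1.3.0 without `--trunc-ok`. `iHS_raw =
ln(iHH_ancestral/iHH_derived)`. nSL replaces the bp integral with the
mean, over carrier pairs, of the shared-interval length in segregating
sites (core + capped runs of at most 100 sites per side);
`nSL_raw = ln(SL_ancestral/SL_derived)`.

The ancestral allele is taken to be the REF allele. This is the module's
major polarity assumption — a reference genome is not an ancestral
genome — and it is why the composite defaults to absolute standardized
scores (below).

Raw scores are z-standardized within derived-allele-frequency bins, per
chromosome: 100 equal-width bins over [0, 1], adjacent bins merged
left-to-right until each holds at least 20 scored cores, population
(divide-by-n) standard deviation. Zero-variance bins leave scores
missing. A single-chromosome dataset therefore normalizes against itself;
on very short chromosomes this weakens sweep scores because the sweep's
own SNPs dominate their frequency bins (see Limitations).

### The DCMS composite

Each statistic is converted to a one-tailed empirical p-value by ranking:
right-tailed `p_i = #{j : v_j ≥ v_i}/(N+1)`, left-tailed with ≤. The
N + 1 denominator keeps p strictly inside (0, 1); ties share a p; the
ranking is genome-wide (all chromosomes jointly). π and Tajima's D are
left-tailed (sweeps depress both). For iHS and nSL the default applies
the right tail to |standardized score|: with reference-based
polarisation the sign of these scores carries no information about
selection, and right-tailing signed scores would systematically discard
sweeps whose favoured allele is the alternate one. `signed_tails=True`
restores the literal signed convention; results differ materially and
the choice is surfaced in the pipeline configuration and run log.

The inter-statistic correlation matrix r is estimated with the Minimum
Covariance Determinant (FAST-MCD, support fraction α = 0.75, fixed seed)
on rows with all four statistics present. The composite is

    DCMS_l = Σ_t logit(1 − p_lt) / w_t ,   w_t = Σ_s |r_st| ≥ 1 ,

so statistics correlated with the others are down-weighted; absolute
correlations prevent sign cancellation in the weights. A
`ratio-of-sums` variant (summed logits over summed weights) is provided
for sensitivity analysis. SNPs missing more than one of the four
statistics are dropped from scoring; with exactly one missing the
composite sums the available terms with their own weights.

DCMS is calibrated by an intercept-only Huber M-estimate (tuning
constant 1.345, scale = MAD/0.6745 re-estimated each IRLS iteration,
convergence 1e−8 or 50 iterations) giving a robust (μ, σ); right-tailed
p-values follow from the normal survivor function. q-values use Storey's
estimator: π0(λ) over λ = 0.05…0.95, cubic-polynomial smoother evaluated
at λ = 0.95 and clipped to (0, 1]; `q_(i) = min_{j≥i} π0·N·p_(j)/j`.
BH is available by fixing π0 = 1.

### Sweep regions

Per chromosome: consecutive significant SNPs (q < 0.05) whose 50 kb bin
indices (`(pos−1)//50000`) differ by at most one form core groups; each
group's span extends outward SNP by SNP absorbing q ≤ 0.10 (the boundary
itself is absorbable), stopping at the first q > 0.10 SNP or the last
scored SNP; regions whose end-exclusive gap is ≤ 50,000 bp merge
transitively. Summaries report the inclusive length `end − start + 1`,
the count of all scored SNPs in the span (a significant-only mode
exists), the minimum q and its position with ties broken toward the
smaller coordinate. Genes are assigned by ≥ 1 bp closed-interval overlap
with GTF gene features.

### QC

The analysis-ready SNP set is defined before any statistic is computed:
GATK-style hard filters on INFO annotations (QD < 2.0, FS > 60.0,
SOR > 4.0, MQ < 40.0, MQRankSum < −12.5, ReadPosRankSum < −8.0, site
DP outside [10, 500], QUAL < 30 — all strict as printed; a rule whose
annotation is absent does not fire), then PLINK-style filtering in the
fixed order sample call rate > 0.9, SNP call rate > 0.9 on the remaining
samples, MAF > 0.05 on the remaining samples (allele counts over
non-missing alleles). The pipeline applies the MAF filter to phased
matrices as well, so the window, iHS and nSL statistics see only the
filtered set — rare variants otherwise break haplotype identity runs
that the statistics rely on.

## The synthetic-data generator

A discrete-generation haploid Wright–Fisher population of
`n_haplotypes_pop = 400` haplotypes on a `chrom_length = 2 Mb`
chromosome. Offspring copy one parent or recombine two (crossovers
Poisson with rate r per bp per generation at uniform breakpoints);
mutations arrive at rate μ per bp per generation at fresh integer
positions (infinite sites, re-drawn on collision, so sites stay
biallelic). A neutral burn-in of 3,200 generations (8N) approaches
mutation–drift equilibrium; for s > 0 a single beneficial copy is then
injected at `sweep_pos` and carriers reproduce with relative fitness
1 + s until frequency ≥ `stop_freq` (default 0.8) or a generation cap;
lost sweeps restart from the post-burn-in state (conditioning on
establishment). A sample of `n_sample = 30` haplotypes (15 diploids, a
typical resequencing cohort for a single breed) is drawn without
replacement and segregating sites emitted as a phased matrix/VCF. Everything is deterministic given the seed.

Default rates are μ = 1.5e−7 per bp per generation, giving a scaled
diversity θ = 2Nμ ≈ 1.2e−4/bp (≈ 1,000 sample SNPs per 2 Mb, about
one-sixteenth of the real data's SNP density), and r = 1e−7 per bp per
generation (ρ/θ ≈ 0.7, in the mammalian genome-average range). The
rates were chosen once so that the generator satisfies its own validity
checks on raw output — neutral Tajima's D centred near zero,
sweep-window π below the chromosome median and near-sweep |iHS|
elevated in a majority of sweep replicates — while keeping EHH
integrable within desk-scale chromosome arms; at substantially lower r
the diversity checks still hold, but EHH stays above its 0.05 cutoff
across an entire 2 Mb chromosome, so nearly every iHS core is skipped
and the robust correlation fit is starved of complete rows. The default sweep position (1,025,000) sits mid-window rather
than on the 50 kb grid boundary at the chromosome midpoint, so the
planted signal is not split across two windows by construction.

What the generator does **not** emulate: demographic history
(bottlenecks, structure, admixture), diploidy and dominance, gene
conversion, variable recombination and mutation maps, genotyping error,
and real SNP density (16× sparser here). Passing tests therefore show
the pipeline's statistics and plumbing are correct at desk scale; they
do not certify power or FDR behaviour on whole-genome resequencing
data.

## End-to-end validation design

Null calibration runs ten single-chromosome neutral replicates (2 Mb,
30 haplotypes) and requires the q < 0.05 fraction to stay below 1% in at
least eight. Sweep recovery embeds one sweep chromosome (s = 0.05,
swept to ≥ 0.8) among two neutral chromosomes per replicate and asks
whether a detected region overlaps the sweep position. The
multi-chromosome genome mirrors real whole-genome scans — genome-wide
ranking and robust calibration are dominated by neutral sequence, as in
real data where sweeps cover a small fraction of the genome — and
guarantees enough complete rows for the MCD fit even when the sweep
chromosome's iHS cores are heavily truncated.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive internally; BED is converted only at
  the file boundary (`bed_start = start − 1`).
* Haplotype columns are ordered (sample1_hapA, sample1_hapB, …); the
  statistics are order-invariant but fixtures are reproducible.
* Missing genotypes in a phased VCF are an error, not imputed.
* EHH pair counting uses identity-run lengths per carrier pair computed
  by chunked vectorised mismatch scans; EHH(d) is the fraction of pairs
  with run length ≥ d. This is exactly equivalent to partition-based
  counting and is what makes chromosome-wide scans fast.
* `stat_to_pvalue` errors on all-missing input; `qvalues` rejects p = 0
  (unreachable via the rank transform); the Huber fit rejects zero-MAD
  samples; MCD requires ≥ 50 complete rows and offers an explicit
  classical-correlation fallback for rank-deficient fits.
* Windowed π of a monomorphic matrix is an empty table, and windows with
  one SNP carry missing D; downstream treats missing as "no evidence".

## Known limitations

* Positional resolution of the composite at desk scale is the local LD
  scale (tens of kb); the strongest SNPs often sit on the sweep's
  recombination shoulders rather than at the swept site itself.
* Incomplete sweeps (frequency ≈ 0.8) depress π only mildly; the π/D
  components contribute weakly until fixation.
* Per-chromosome frequency-bin standardization on short chromosomes
  partially absorbs the sweep's own signal (its SNPs dominate their
  bins); the selscan-style per-chromosome convention is kept, with a
  pooling flag.
* The normal calibration of DCMS is an approximation to a heavy-tailed
  distribution; extreme-tail p-values are optimistic, which Storey's
  q-values only partly offset. The null-calibration test bounds the
  practical consequence.
* Small ancestral classes at high-frequency cores make iHS noisy; cores
  with MAF < 0.05 are excluded entirely.
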