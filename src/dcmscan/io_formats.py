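"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
Internal coordinates are 1-based inclusive everywhere (the native VCF and
GTF convention). BED's 0-based half-open convention is applied only at the
file boundary: ``bed_start = start - 1``, ``bed_end = end``. Chromosome
names are opaque strings; no prefix is assumed or stripped.

Haplotype columns are ordered ``(sample1_hapA, sample1_hapB, sample2_hapA,
...)``. iHS/nSL are invariant to haplotype order, but the ordering is fixed
so fixtures are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

# INFO keys carried through for hard filtering when present in the VCF.
INFO_KEYS = ("QD", "FS", "SOR", "MQ", "MQRankSum", "ReadPosRankSum", "DP")


@dataclass
class VariantSite:
    """One biallelic SNP record with the INFO fields QC needs."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    qual: float | None = None
    info_fields: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele must differ from alt_allele")


@dataclass
class HaplotypeMatrix:
    """Phased 0/1 allele matrix, haplotypes x sites.

    ``alleles[h, m]`` is 0 for the reference allele and 1 for the alternate
    allele of haplotype ``h`` at the m-th site. Two haplotypes per diploid
    sample; ``positions`` are 1-based and strictly increasing.
    """

    chrom: str
    positions: np.ndarray  # (M,) int64, strictly increasing, 1-based
    alleles: np.ndarray  # (H, M) uint8 in {0, 1}
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D haplotypes x sites matrix")
        h, m = self.alleles.shape
        if m != self.positions.size:
            raise ValueError("positions length must match number of sites")
        if h % 2 != 0:
            raise ValueError("number of haplotypes must be even (diploid samples)")
        if len(self.sample_ids) != h // 2:
            raise ValueError("need one sample id per haplotype pair")
        if m > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.alleles.size and not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be 0/1 with no missing entries")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]


@dataclass
class GeneRecord:
    """A gene interval from a GTF, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


def read_phased_vcf(
    path: str, chrom_filter: str | None = None
) -> tuple[dict[str, HaplotypeMatrix], list[VariantSite], dict[str, int]]:
    """Read a phased VCF into per-chromosome haplotype matrices.

    Only biallelic SNP records are retained; multiallelic records and
    indels are skipped and counted. An unphased genotype at a retained
    site raises, naming the site: phasing is an upstream contract, not
    something this reader repairs.

    Returns
    -------
    matrices : dict chrom -> HaplotypeMatrix
    sites : list of VariantSite (all chromosomes, input order)
    skipped : dict with counts ``{"multiallelic": ..., "non_snp": ...}``
    """
    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    skipped = {"multiallelic": 0, "non_snp": 0}
    per_chrom: dict[str, tuple[list[int], list[np.ndarray]]] = {}
    sites: list[VariantSite] = []

    for v in vcf:
        if chrom_filter is not None and v.CHROM != chrom_filter:
            continue
        if len(v.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped["non_snp"] += 1
            continue
        gts = v.genotypes  # [[a, b, phased], ...]
        haps = np.empty(2 * len(gts), dtype=np.uint8)
        for i, gt in enumerate(gts):
            a, b, phased = gt[0], gt[1], gt[-1]
            if a < 0 or b < 0:
                raise ValueError(
                    f"missing genotype at {v.CHROM}:{v.POS} (sample {sample_ids[i]}); "
                    "run QC/phasing upstream"
                )
            if not phased:
                raise ValueError(
                    f"unphased genotype at {v.CHROM}:{v.POS} (sample {sample_ids[i]})"
                )
            haps[2 * i] = a
            haps[2 * i + 1] = b
        info = {}
        for key in INFO_KEYS:
            val = v.INFO.get(key)
            if val is not None:
                info[key] = float(val)
        sites.append(
            VariantSite(
                chrom=v.CHROM,
                pos=v.POS,
                ref_allele=v.REF,
                alt_allele=v.ALT[0],
                qual=None if v.QUAL is None else float(v.QUAL),
                info_fields=info,
            )
        )
        pos_list, col_list = per_chrom.setdefault(v.CHROM, ([], []))
        pos_list.append(v.POS)
        col_list.append(haps)

    if skipped["multiallelic"] or skipped["non_snp"]:
        logger.info(
            "read_phased_vcf(%s): skipped %d multiallelic, %d non-SNP records",
            path, skipped["multiallelic"], skipped["non_snp"],
        )

    matrices = {}
    for chrom, (pos_list, col_list) in per_chrom.items():
        matrices[chrom] = HaplotypeMatrix(
            chrom=chrom,
            positions=np.array(pos_list, dtype=np.int64),
            alleles=np.column_stack(col_list).astype(np.uint8),
            sample_ids=sample_ids,
        )
    return matrices, sites, skipped


def write_phased_vcf(
    matrices: dict[str, HaplotypeMatrix] | HaplotypeMatrix,
    path: str,
    ref_allele: str = "A",
    alt_allele: str = "G",
    sites: list[VariantSite] | None = None,
) -> None:
    """Write haplotype matrices as a phased VCF v4.2 text file.

    Synthetic matrices carry no nucleotide identity, so placeholder
    REF/ALT bases are used unless matching ``sites`` records are given.
    """
    if isinstance(matrices, HaplotypeMatrix):
        matrices = {matrices.chrom: matrices}
    first = next(iter(matrices.values()))
    sample_ids = first.sample_ids
    site_lookup: dict[tuple[str, int], VariantSite] = {}
    if sites is not None:
        site_lookup = {(s.chrom, s.pos): s for s in sites}

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in matrices:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids) + "\n"
        )
        for chrom, mat in matrices.items():
            if mat.sample_ids != sample_ids:
                raise ValueError("all matrices must share one sample set")
            for j in range(mat.n_sites):
                pos = int(mat.positions[j])
                site = site_lookup.get((chrom, pos))
                ref = site.ref_allele if site else ref_allele
                alt = site.alt_allele if site else alt_allele
                qual = "." if site is None or site.qual is None else f"{site.qual:g}"
                col = mat.alleles[:, j]
                gts = "\t".join(
                    f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(len(sample_ids))
                )
                fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\tPASS\t.\tGT\t{gts}\n")


def write_regions_bed(regions, path: str) -> None:
    """Write sweep regions as BED3 (0-based half-open), sorted by (chrom, start).

    Overlapping regions on one chromosome are an error: merging is a
    contract of the region builder, not of the writer.
    """
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start))
    prev_by_chrom: dict[str, int] = {}
    for r in ordered:
        if r.chrom in prev_by_chrom and r.start <= prev_by_chrom[r.chrom]:
            raise ValueError(
                f"overlapping regions on {r.chrom} at start {r.start}; merge upstream"
            )
        prev_by_chrom[r.chrom] = r.end
    with open(path, "w") as fh:
        for r in ordered:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\n")


def read_regions_bed(path: str) -> list[tuple[str, int, int]]:
    """Read BED3 back into 1-based inclusive (chrom, start, end) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, bed_start, bed_end = line.split("\t")[:3]
            out.append((chrom, int(bed_start) + 1, int(bed_end)))
    return out


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gtf_genes(path: str) -> list[GeneRecord]:
    """Extract ``gene`` features from a GTF as 1-based inclusive records.

    A gene feature without a ``gene_id`` attribute raises, naming the line
    number; comment lines are ignored; non-gene features (transcripts,
    exons, ...) are skipped.
    """
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "gene":
                continue
            attributes = _parse_gtf_attributes(attrs)
            if "gene_id" not in attributes:
                raise ValueError(f"{path}:{lineno}: gene feature without gene_id attribute")
            genes.append(
                GeneRecord(
                    gene_id=attributes["gene_id"],
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand if strand in ("+", "-") else ".",
                )
            )
    return genes
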