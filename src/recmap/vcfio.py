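"""Thin VCF adapters: trio genotypes, phased haplotypes, genotype matrices.

Reading goes through cyvcf2; writing produces minimal plain-text VCF 4.2
(sufficient for the synthetic-data workflows and for hand inspection).
Multi-allelic and non-SNP records are skipped with a count.
"""

from __future__ import annotations

import logging

import numpy as np
from cyvcf2 import VCF

from recmap.phasing import GenotypeMatrix, PhasedSample

logger = logging.getLogger(__name__)


def _snp_records(path: str, region: str | None):
    vcf = VCF(path)
    samples = list(vcf.samples)
    n_skipped = 0
    it = vcf(region) if region else vcf
    for variant in it:
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            n_skipped += 1
            continue
        yield samples, variant
    if n_skipped:
        logger.info("%s: skipped %d non-biallelic-SNP records", path, n_skipped)


def read_genotype_matrix(path: str, region: str | None = None) -> GenotypeMatrix:
    """Load unphased biallelic-SNP genotypes for all samples in a VCF."""
    positions: list[int] = []
    rows: list[np.ndarray] = []
    samples: list[str] = []
    chrom = region.split(":")[0] if region else None
    for samples, variant in _snp_records(path, region):
        if chrom is None:
            chrom = variant.CHROM
        elif variant.CHROM != chrom:
            continue
        gt = np.asarray([g[:2] for g in variant.genotypes], dtype=np.int8)
        positions.append(variant.POS)
        rows.append(gt)
    if not positions:
        raise ValueError(f"{path}: no biallelic SNPs found")
    return GenotypeMatrix(chrom, np.asarray(positions), samples,
                          np.stack(rows, axis=0))


def read_phased_sample(path: str, sample: str, region: str | None = None) -> PhasedSample:
    """Load one sample's phased haplotypes ('|'-separated GT) from a VCF.

    Unphased or missing genotypes for the sample are skipped.
    """
    positions: list[int] = []
    hap1: list[int] = []
    hap2: list[int] = []
    chrom = region.split(":")[0] if region else None
    for samples, variant in _snp_records(path, region):
        if sample not in samples:
            raise ValueError(f"{path}: sample {sample!r} not present")
        idx = samples.index(sample)
        if chrom is None:
            chrom = variant.CHROM
        elif variant.CHROM != chrom:
            continue
        row = variant.genotypes[idx]
        a, b, phased = int(row[0]), int(row[1]), bool(row[2])
        if not phased or a < 0 or b < 0:
            continue
        positions.append(variant.POS)
        hap1.append(a)
        hap2.append(b)
    return PhasedSample(chrom or "", np.asarray(positions, dtype=np.int64),
                        np.asarray(hap1, dtype=np.int8),
                        np.asarray(hap2, dtype=np.int8))


def write_vcf(
    path: str,
    matrix: GenotypeMatrix,
    phased: bool = False,
    contig_length: int | None = None,
) -> None:
    """Write a genotype matrix as a minimal uncompressed VCF.

    With ``phased=True`` the two allele columns are emitted as ordered
    haplotypes ('|'); otherwise as unphased genotypes ('/').  All sites are
    written as A→G SNPs — allele identity is irrelevant to the analyses here.
    """
    sep = "|" if phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        length = contig_length or int(matrix.positions[-1]) + 1
        fh.write(f"##contig=<ID={matrix.chromosome},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for i, pos in enumerate(matrix.positions):
            gts = []
            for a, b in matrix.genotypes[i]:
                sa = "." if a < 0 else str(int(a))
                sb = "." if b < 0 else str(int(b))
                gts.append(f"{sa}{sep}{sb}")
            fh.write(f"{matrix.chromosome}\t{pos}\t.\tA\tG\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
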