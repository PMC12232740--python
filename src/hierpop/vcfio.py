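"""Readers and writers for the standard on-disk formats.

Genotypes travel as VCF v4.2 (read through cyvcf2); hierarchy, phenotype,
climate and geography tables as tab-separated text with a header line.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    MISSING,
    ClimateMatrix,
    GenotypeMatrix,
    HaplotypeSet,
    PhenotypeRecords,
    SampleHierarchy,
    VariantMap,
)

log = logging.getLogger("hierpop")


def read_vcf(path, region: str | None = None):
    """Read biallelic diploid SNPs from a VCF.

    Returns ``(GenotypeMatrix, HaplotypeSet | None)``; the haplotype set is
    populated only when every record is fully phased. Non-biallelic records are
    skipped (counted in the log); malformed files raise from the parser.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, poss, refs, alts = [], [], [], []
    dose_rows, hap_a, hap_b = [], [], []
    phased = True
    n_skipped = 0
    it = vcf(region) if region else vcf
    for var in it:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        g = np.array(var.genotypes, dtype=np.int16)  # columns: allele1, allele2, phased
        a, b = g[:, 0], g[:, 1]
        miss = (a < 0) | (b < 0)
        d = np.where(miss, MISSING, a + b).astype(np.int8)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        dose_rows.append(d)
        if phased and g.shape[1] >= 3 and bool(np.all(g[:, 2] == 1)) and not miss.any():
            hap_a.append(a.astype(np.int8))
            hap_b.append(b.astype(np.int8))
        else:
            phased = False
    vcf.close()
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic records", n_skipped)
    if not poss:
        raise ValueError(f"no biallelic SNP records in {path}")
    vm = VariantMap(np.array(chroms), np.array(poss), np.array(refs), np.array(alts))
    gm = GenotypeMatrix(np.column_stack(dose_rows), vm, samples)
    hs = None
    if phased:
        h = np.empty((2 * len(samples), vm.n_snps), dtype=np.int8)
        h[0::2] = np.column_stack(hap_a)
        h[1::2] = np.column_stack(hap_b)
        hs = HaplotypeSet(h, vm, samples)
    return gm, hs


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(path, gm: GenotypeMatrix, haplotypes: HaplotypeSet | None = None) -> None:
    """Write a minimal VCF v4.2; phased GT fields when haplotypes are given."""
    path = Path(path)
    vm = gm.variants
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in pd.unique(vm.chrom):
            n = int(vm.pos[vm.chrom == c].max())
            fh.write(f"##contig=<ID={c},length={n + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.sample_ids) + "\n")
        for j in range(vm.n_snps):
            if haplotypes is not None:
                ha = haplotypes.haplotypes[0::2, j]
                hb = haplotypes.haplotypes[1::2, j]
                gts = [f"{a}|{b}" for a, b in zip(ha, hb)]
            else:
                lut = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                gts = [lut[int(d)] for d in gm.dosages[:, j]]
            row = [
                str(vm.chrom[j]),
                str(int(vm.pos[j])),
                f"snp{j}",
                str(vm.ref[j]),
                str(vm.alt[j]),
                ".",
                ".",
                ".",
                "GT",
            ]
            fh.write("\t".join(row) + "\t" + "\t".join(gts) + "\n")


def read_hierarchy(path) -> SampleHierarchy:
    return SampleHierarchy(pd.read_csv(path, sep="\t", dtype={"genotype": str, "stand": str, "river": str}))


def write_hierarchy(path, hierarchy: SampleHierarchy) -> None:
    hierarchy.table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeRecords:
    return PhenotypeRecords(pd.read_csv(path, sep="\t", dtype={"genotype": str, "site": str}))


def write_phenotypes(path, records: PhenotypeRecords) -> None:
    records.table.to_csv(path, sep="\t", index=False)


def read_climate(path) -> ClimateMatrix:
    t = pd.read_csv(path, sep="\t", index_col=0)
    t.index = t.index.astype(str)
    return ClimateMatrix(t)


def write_climate(path, climate: ClimateMatrix) -> None:
    climate.table.to_csv(path, sep="\t")
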