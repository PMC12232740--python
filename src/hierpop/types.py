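"""Core in-memory containers shared by all analysis stages.

The package works on diploid, biallelic SNP data for clonally replicated
genotypes sampled in a two-level geographic hierarchy: genotypes belong to
stands (local groups of trees) and stands belong to rivers (drainages).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for missing dosage


@dataclass
class VariantMap:
    """Per-SNP coordinates and alleles (1-based positions, VCF convention)."""

    chrom: np.ndarray  # str array
    pos: np.ndarray  # int, 1-based
    ref: np.ndarray  # str
    alt: np.ndarray  # str

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_snps(self) -> int:
        return self.pos.size

    def take(self, idx) -> "VariantMap":
        return VariantMap(self.chrom[idx], self.pos[idx], self.ref[idx], self.alt[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "ref": self.ref, "alt": self.alt}
        )


@dataclass
class GenotypeMatrix:
    """Alt-allele dosage matrix (individuals x SNPs), values in {0,1,2} or -1."""

    dosages: np.ndarray
    variants: VariantMap
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if self.dosages.shape[1] != self.variants.n_snps:
            raise ValueError("dosage columns do not match variant map")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("dosage rows do not match sample ids")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per SNP, ignoring missing calls."""
        d = np.ma.masked_equal(self.dosages, MISSING)
        return np.asarray(d.mean(axis=0) / 2.0)

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def imputed(self, dtype=np.float64) -> np.ndarray:
        """Dosages with per-SNP mean imputation of missing calls."""
        x = self.dosages.astype(dtype)
        miss = self.dosages == MISSING
        if miss.any():
            p2 = 2.0 * self.allele_frequencies()
            idx = np.where(miss)
            x[idx] = p2[idx[1]]
        return x

    def take_snps(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[:, idx], self.variants.take(idx), self.sample_ids)

    def take_samples(self, idx) -> "GenotypeMatrix":
        ids = [self.sample_ids[i] for i in np.atleast_1d(np.asarray(idx))]
        return GenotypeMatrix(self.dosages[np.asarray(idx)], self.variants, ids)


@dataclass
class HaplotypeSet:
    """Phased haplotypes, rows 2i and 2i+1 hold the two haplotypes of sample i."""

    haplotypes: np.ndarray  # (2n x m) in {0,1}
    variants: VariantMap
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("haplotype rows must be 2 x samples")
        if self.haplotypes.shape[1] != self.variants.n_snps:
            raise ValueError("haplotype columns do not match variant map")

    def to_genotypes(self) -> GenotypeMatrix:
        d = self.haplotypes[0::2] + self.haplotypes[1::2]
        return GenotypeMatrix(d, self.variants, self.sample_ids)

    def take_snps(self, idx) -> "HaplotypeSet":
        return HaplotypeSet(self.haplotypes[:, idx], self.variants.take(idx), self.sample_ids)


@dataclass
class SampleHierarchy:
    """genotype -> stand -> river assignment with source-location geography."""

    table: pd.DataFrame  # columns: genotype, stand, river, latitude, longitude, elevation

    REQUIRED = ("genotype", "stand", "river", "latitude", "longitude", "elevation")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"hierarchy table missing columns: {missing}")
        if self.table["genotype"].duplicated().any():
            raise ValueError("each genotype must appear exactly once")
        # every stand maps to exactly one river
        per_stand = self.table.groupby("stand")["river"].nunique()
        if (per_stand > 1).any():
            bad = per_stand[per_stand > 1].index.tolist()
            raise ValueError(f"stands assigned to multiple rivers: {bad}")
        self.table = self.table.reset_index(drop=True)

    @property
    def genotypes(self) -> np.ndarray:
        return self.table["genotype"].to_numpy()

    @property
    def stands(self) -> np.ndarray:
        return self.table["stand"].to_numpy()

    @property
    def rivers(self) -> np.ndarray:
        return self.table["river"].to_numpy()

    def aligned_to(self, sample_ids: Sequence[str]) -> "SampleHierarchy":
        t = self.table.set_index("genotype").loc[list(sample_ids)].reset_index()
        return SampleHierarchy(t)

    def river_of_stand(self) -> pd.Series:
        return self.table.groupby("stand")["river"].first()

    def river_latitudes(self) -> pd.Series:
        return self.table.groupby("river")["latitude"].mean()


@dataclass
class PhenotypeRecords:
    """Long-format clonal-trial observations: genotype, site, year, trait, value."""

    table: pd.DataFrame

    REQUIRED = ("genotype", "site", "year", "trait", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    def traits(self) -> list[str]:
        return sorted(self.table["trait"].unique())

    def year_means(self, trait: str) -> pd.DataFrame:
        """Average multi-year values per genotype-site before model fitting."""
        t = self.table[self.table["trait"] == trait]
        cols = ["genotype", "site"]
        if "ramet" in t.columns:
            cols.append("ramet")
        return t.groupby(cols, as_index=False)["value"].mean()


@dataclass
class ClimateMatrix:
    """Per-genotype (or per-stand) climate variables, complete after imputation."""

    table: pd.DataFrame  # index: genotype or stand id; columns: climate variables

    def __post_init__(self) -> None:
        if self.table.isna().any().any():
            raise ValueError("climate matrix contains missing values")

    @property
    def variables(self) -> list[str]:
        return list(self.table.columns)

    def values_for(self, ids: Sequence[str]) -> np.ndarray:
        return self.table.loc[list(ids)].to_numpy(dtype=float)


@dataclass
class FilterSpec:
    """Marker-filtering recipe applied in a fixed order.

    Order: MAF floor, singleton removal, distance thinning (greedy left-to-right),
    LD pruning (sliding window, drop the later SNP of a correlated pair), then an
    optional uniform random subsample of fixed size.
    """

    min_maf: float = 0.0
    drop_singletons: bool = False
    thin_bp: int = 0
    ld_r2: float | None = None
    ld_window: int = 50
    ld_step: int = 10
    subsample: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_maf < 0.5):
            raise ValueError("min_maf must be in [0, 0.5)")
        if self.thin_bp < 0:
            raise ValueError("thin_bp must be >= 0")
        if self.ld_r2 is not None and not (0.0 < self.ld_r2 <= 1.0):
            raise ValueError("ld_r2 must be in (0, 1]")
        if self.subsample is not None and self.subsample <= 0:
            raise ValueError("subsample must be positive")
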