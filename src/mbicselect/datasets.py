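"""In-memory containers for additive-coded genotype data.

Genotypes are stored as an ``n x p`` float matrix counting copies of allele1
(0/1/2); missing calls are ``numpy.nan``.  SNP metadata lives in a pandas
DataFrame with one row per SNP, in matrix column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

SNP_COLUMNS = ["snp_id", "chrom", "pos_bp", "allele1", "allele2"]


class SnpInfo(NamedTuple):
    """Metadata for one SNP (position 1-based, alleles single characters)."""

    snp_id: str
    chrom: str
    pos_bp: int
    allele1: str
    allele2: str


def snp_table(snps) -> pd.DataFrame:
    """Build a SNP metadata DataFrame from SnpInfo records (or pass one through)."""
    if isinstance(snps, pd.DataFrame):
        df = snps.reset_index(drop=True)
        missing = [c for c in SNP_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"SNP table missing columns: {missing}")
        return df
    return pd.DataFrame([SnpInfo(*s) for s in snps], columns=SNP_COLUMNS)


@dataclass
class GenotypeDataset:
    """An additive-coded case-control genotype dataset.

    Parameters
    ----------
    genotypes : ndarray of shape (n, p)
        Counts of allele1 in {0, 1, 2}; missing entries are NaN.
    snps : DataFrame with columns snp_id, chrom, pos_bp, allele1, allele2
        One row per genotype column, in column order.
    phenotype : ndarray of shape (n,)
        Disease status, 0 = control, 1 = case.
    """

    genotypes: np.ndarray
    snps: pd.DataFrame
    phenotype: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        self.snps = snp_table(self.snps)
        self.phenotype = np.asarray(self.phenotype)
        n, p = self.genotypes.shape
        if len(self.snps) != p:
            raise ValueError(f"snps has {len(self.snps)} rows but genotypes has {p} columns")
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype length must match the number of individuals")
        if not np.isin(self.phenotype, [0, 1]).all():
            raise ValueError("phenotype must be binary 0 (control) / 1 (case)")
        if not self.snps["snp_id"].is_unique:
            raise ValueError("snp_id values must be unique")
        valid = self.genotypes[~np.isnan(self.genotypes)]
        if valid.size and (valid.min() < 0 or valid.max() > 2):
            raise ValueError("genotype entries must lie in [0, 2] or be NaN")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def p(self) -> int:
        return self.genotypes.shape[1]

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP, from non-missing calls only."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.genotypes, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset_snps(self, indices) -> "GenotypeDataset":
        """New dataset restricted to the given SNP columns (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return GenotypeDataset(
            self.genotypes[:, idx],
            self.snps.iloc[idx].reset_index(drop=True),
            self.phenotype.copy(),
        )

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            self.genotypes.copy(), self.snps.copy(), self.phenotype.copy()
        )
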