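"""Quality-control filtering and missing-genotype imputation."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datasets import GenotypeDataset


def hwe_pvalues(ds: GenotypeDataset) -> np.ndarray:
    """Hardy-Weinberg 1-df chi-square goodness-of-fit p-value per SNP.

    Genotype counts are pooled over cases and controls and restricted to
    non-missing calls; expected counts come from the sample allele frequency.
    Monomorphic SNPs get p = 1 (observed equals expected exactly).
    """
    g = ds.genotypes
    obs = np.stack([np.nansum(g == v, axis=0) for v in (0.0, 1.0, 2.0)]).astype(float)
    n_called = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = (obs[1] + 2 * obs[2]) / (2 * n_called)  # allele1 frequency
        exp = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2]) * n_called
        terms = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
    chi2 = terms.sum(axis=0)
    pvals = stats.chi2.sf(chi2, df=1)
    pvals[n_called == 0] = np.nan
    return pvals


def qc_filter(
    ds: GenotypeDataset, maf_min: float = 0.01, hwe_alpha: float = 1e-4
) -> GenotypeDataset:
    """Keep SNPs with MAF >= ``maf_min`` and HWE p-value >= ``hwe_alpha``.

    Defaults match common GWAS preprocessing (MAF 0.01, HWE alpha 1e-4).
    SNP order is preserved; the result may be empty.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must lie in [0, 0.5)")
    if not 0 < hwe_alpha < 1:
        raise ValueError("hwe_alpha must lie in (0, 1)")
    maf = ds.maf()
    hwe = hwe_pvalues(ds)
    keep = np.flatnonzero((maf >= maf_min) & (hwe >= hwe_alpha))
    return ds.subset_snps(keep)


def impute_missing(ds: GenotypeDataset) -> GenotypeDataset:
    """Replace each missing call with the SNP's mean genotype.

    Raises ``ValueError`` naming the SNP if a column has no observed calls.
    """
    g = ds.genotypes
    missing = np.isnan(g)
    if not missing.any():
        return ds.copy()
    n_obs = (~missing).sum(axis=0)
    all_missing = np.flatnonzero(n_obs == 0)
    if all_missing.size:
        ids = ds.snps["snp_id"].iloc[all_missing].tolist()
        raise ValueError(f"SNP(s) with all genotypes missing: {ids}")
    col_means = np.nanmean(g, axis=0)
    out = np.where(missing, col_means[None, :], g)
    return GenotypeDataset(out, ds.snps.copy(), ds.phenotype.copy())
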