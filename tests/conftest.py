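import numpy as np
import pandas as pd
import pytest

from mbicselect.datasets import GenotypeDataset


def make_dataset(genotypes, phenotype, chrom=None, pos=None) -> GenotypeDataset:
    """Build a GenotypeDataset from raw arrays with generated metadata."""
    genotypes = np.asarray(genotypes, dtype=float)
    p = genotypes.shape[1]
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(p)],
            "chrom": "1" if chrom is None else chrom,
            "pos_bp": np.arange(1, p + 1) * 1000 if pos is None else pos,
            "allele1": "A",
            "allele2": "B",
        }
    )
    return GenotypeDataset(genotypes, snps, np.asarray(phenotype))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_dataset(rng, n=30, p=4, maf=0.3, missing=0.0) -> GenotypeDataset:
    g = rng.binomial(2, maf, size=(n, p)).astype(float)
    if missing:
        mask = rng.random((n, p)) < missing
        g[mask] = np.nan
    y = rng.integers(0, 2, size=n)
    if y.min() == y.max():  # ensure both classes present
        y[0] = 1 - y[0]
    return make_dataset(g, y)
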