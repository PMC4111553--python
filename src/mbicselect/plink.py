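"""PLINK binary trio (.bed/.bim/.fam) reader and writer.

The .bed payload is SNP-major: per SNP, ceil(n/4) bytes, four samples per
byte packed from the least significant bit pair.  Two-bit codes map to
allele1 counts as 00 -> 2, 10 -> 1, 11 -> 0, 01 -> missing.  On-disk .fam
phenotype is 1 = control / 2 = case and is mapped to 0/1 in memory.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datasets import GenotypeDataset, snp_table

_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# allele1-count for each 2-bit code 00, 01, 10, 11
_CODE_TO_GENO = np.array([2.0, np.nan, 1.0, 0.0])


class PlinkFormatError(ValueError):
    """Raised when a .bed/.bim/.fam file violates the PLINK binary format."""


def _require(path: str) -> str:
    if not os.path.exists(path):
        raise FileNotFoundError(f"PLINK file not found: {path}")
    return path


def read_plink(path_prefix: str) -> GenotypeDataset:
    """Read a PLINK binary trio ``path_prefix``.{bed,bim,fam}.

    Returns a :class:`GenotypeDataset` with genotypes counting the .bim A1
    allele, samples in .fam order and SNPs in .bim order.
    """
    bim = pd.read_csv(
        _require(path_prefix + ".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos_bp", "allele1", "allele2"],
        dtype={"chrom": str, "snp_id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        _require(path_prefix + ".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
    )
    n, p = len(fam), len(bim)

    pheno_disk = fam["phenotype"].to_numpy()
    if not np.isin(pheno_disk, [1, 2]).all():
        raise PlinkFormatError(
            f"{path_prefix}.fam: phenotype must be 1 (control) or 2 (case)"
        )

    with open(_require(path_prefix + ".bed"), "rb") as fh:
        raw = fh.read()
    if len(raw) < 3 or raw[:2] != _MAGIC:
        raise PlinkFormatError(f"{path_prefix}.bed: bad magic bytes")
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(f"{path_prefix}.bed: not in SNP-major mode")

    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_snp * p:
        raise PlinkFormatError(
            f"{path_prefix}.bed: expected {bytes_per_snp * p} payload bytes "
            f"for n={n}, p={p}, found {payload.size}"
        )

    if p:
        mat = payload.reshape(p, bytes_per_snp)
        # unpack the four 2-bit fields of every byte, LSB pair first
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
        codes = (mat[:, :, None] >> shifts) & 0b11
        codes = codes.reshape(p, bytes_per_snp * 4)[:, :n]
        genotypes = _CODE_TO_GENO[codes].T
    else:
        genotypes = np.empty((n, 0))

    snps = bim[["snp_id", "chrom", "pos_bp", "allele1", "allele2"]]
    return GenotypeDataset(genotypes, snps, (pheno_disk == 2).astype(np.int8))


def write_plink(ds: GenotypeDataset, path_prefix: str) -> None:
    """Write ``ds`` as a PLINK binary trio readable by :func:`read_plink`.

    Non-integer (e.g. mean-imputed) genotype values cannot be represented in
    the 2-bit code and raise ``ValueError``.
    """
    n, p = ds.n, ds.p
    geno = ds.genotypes
    finite = geno[~np.isnan(geno)]
    if finite.size and not np.isin(finite, [0.0, 1.0, 2.0]).all():
        raise ValueError("write_plink requires genotypes in {0, 1, 2, NaN}")

    snps = ds.snps
    bim = pd.DataFrame(
        {
            "chrom": snps["chrom"],
            "snp_id": snps["snp_id"],
            "cm": 0,
            "pos_bp": snps["pos_bp"],
            "allele1": snps["allele1"],
            "allele2": snps["allele2"],
        }
    )
    bim.to_csv(path_prefix + ".bim", sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": [f"F{i + 1}" for i in range(n)],
            "iid": [f"I{i + 1}" for i in range(n)],
            "father": 0,
            "mother": 0,
            "sex": 0,
            "phenotype": np.asarray(ds.phenotype) + 1,
        }
    )
    fam.to_csv(path_prefix + ".fam", sep="\t", header=False, index=False)

    # genotype -> 2-bit code: 2 -> 00, 1 -> 10, 0 -> 11, NaN -> 01
    codes = np.full((p, n), 0b01, dtype=np.uint8)
    g = geno.T
    codes[g == 2.0] = 0b00
    codes[g == 1.0] = 0b10
    codes[g == 0.0] = 0b11

    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((p, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    padded = padded.reshape(p, bytes_per_snp, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (padded << shifts).sum(axis=2).astype(np.uint8)

    with open(path_prefix + ".bed", "wb") as fh:
        fh.write(_MAGIC)
        fh.write(bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())
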