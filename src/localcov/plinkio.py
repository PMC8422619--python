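"""Minimal reader/writer for the PLINK 1 binary genotype format.

A panel is the triplet ``prefix.bed`` / ``prefix.bim`` / ``prefix.fam``.
The .bed payload is SNP-major: one SNP per row of ``ceil(n/4)`` bytes,
four samples per byte, two bits per sample, least-significant pair first.
Dosages count copies of the A1 allele (column 5 of the .bim):

    0b00 -> 2 (homozygous A1)
    0b01 -> missing (NaN)
    0b10 -> 1 (heterozygous)
    0b11 -> 0 (homozygous A2)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_MAGIC = bytes([0x6C, 0x1B, 0x01])

BIM_COLUMNS = ["chrom", "snp", "cm", "pos", "a1", "a2"]
FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]

# decoded dosage for each 2-bit code, NaN marks missing
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def read_bim(path) -> pd.DataFrame:
    bim = pd.read_csv(path, sep=r"\s+", header=None, names=BIM_COLUMNS,
                      dtype={"chrom": str, "snp": str, "a1": str, "a2": str})
    bim["chrom"] = bim["chrom"].str.replace("chr", "", regex=False)
    return bim


def read_fam(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", header=None, names=FAM_COLUMNS)


def read_bed(prefix: str):
    """Read a PLINK triplet.

    Returns
    -------
    dosages : (n_samples, n_snps) float array, NaN for missing
    bim : DataFrame with columns chrom, snp, cm, pos, a1, a2
    fam : DataFrame with columns fid, iid, father, mother, sex, phenotype
    """
    bim = read_bim(f"{prefix}.bim")
    fam = read_fam(f"{prefix}.fam")
    n, m = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        raw = fh.read()
    if raw[:3] != _MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK 1 .bed file")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_snp:
        raise ValueError(
            f"{prefix}.bed has {body.size} payload bytes, "
            f"expected {m * bytes_per_snp} for {n} samples x {m} SNPs")
    body = body.reshape(m, bytes_per_snp)
    # expand each byte into its four 2-bit codes, sample index fastest
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts) & 0b11
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    return _CODE_TO_DOSAGE[codes].T.copy(), bim, fam


def write_bed(prefix: str, dosages: np.ndarray, bim: pd.DataFrame,
              fam: pd.DataFrame | None = None) -> None:
    """Write a PLINK triplet; ``dosages`` is (n_samples, n_snps), NaN = missing."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if len(bim) != m:
        raise ValueError(f".bim has {len(bim)} rows for {m} SNP columns")
    if fam is None:
        fam = pd.DataFrame({
            "fid": [f"F{i}" for i in range(n)],
            "iid": [f"I{i}" for i in range(n)],
            "father": 0, "mother": 0, "sex": 0, "phenotype": -9,
        })
    if len(fam) != n:
        raise ValueError(f".fam has {len(fam)} rows for {n} sample rows")

    # dosage -> 2-bit code
    codes = np.full(dosages.shape, 0b01, dtype=np.uint8)  # missing
    codes[dosages == 2] = 0b00
    codes[dosages == 1] = 0b10
    codes[dosages == 0] = 0b11
    codes = codes.T  # SNP-major
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    padded[:, n:] = 0b00  # pad bits are ignored on read
    packed = (padded.reshape(m, bytes_per_snp, 4)
              << np.array([0, 2, 4, 6], dtype=np.uint8)).sum(
                  axis=2, dtype=np.uint32).astype(np.uint8)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False,
               columns=BIM_COLUMNS)
    fam.to_csv(f"{prefix}.fam", sep="\t", header=False, index=False,
               columns=FAM_COLUMNS)


def panel_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per SNP from a dosage matrix (missing ignored)."""
    p = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)
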