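"""Reading, quality control and harmonization of GWAS summary statistics.

Summary statistics are whitespace/tab-delimited text with (at least) the
columns SNP, A1, A2, Z, N — the layout produced by the usual munging
scripts. Two studies are analysed jointly after restricting to the SNPs
shared by both studies and the LD reference panel, matching effect
alleles between studies (flipping z-score signs where the allele pair is
swapped) and removing strand-ambiguous variants, rare variants and the
MHC region.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
#: allele pairs that are their own reverse complement and therefore cannot
#: be oriented across strands
AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

#: extended MHC on chromosome 6, half-open bp window (build of the panel)
DEFAULT_MHC = (6, 25_000_000, 35_000_000)

_REQUIRED = ("SNP", "A1", "A2", "Z", "N")
_ALIASES = {
    "SNP": {"SNP", "RSID", "ID", "MARKERNAME"},
    "A1": {"A1", "EFFECT_ALLELE", "ALLELE1"},
    "A2": {"A2", "OTHER_ALLELE", "ALLELE2", "ALLELE0"},
    "Z": {"Z", "ZSCORE", "Z_SCORE"},
    "N": {"N", "NEFF", "N_TOTAL"},
}


class SchemaError(ValueError):
    """A required summary-statistics column is missing."""


@dataclass
class HarmonizedPair:
    """Two aligned z-score vectors over a shared, QC'd SNP set.

    ``table`` has one row per retained SNP with columns
    (snp, chrom, pos, z1, z2), ordered by genome position.
    """

    table: pd.DataFrame
    n1: int
    n2: int
    counts: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.table)


@dataclass
class GenomePartition:
    """Ordered, non-overlapping genome blocks (chrom, start, stop), 1-based
    half-open ``[start, stop)`` intervals."""

    blocks: pd.DataFrame  # columns chrom, start, stop

    def __len__(self) -> int:
        return len(self.blocks)


def read_sumstats(path) -> pd.DataFrame:
    """Read one summary-statistics file into (snp, a1, a2, z, n).

    Rows with missing/non-finite z, invalid alleles (indel codes, identical
    alleles) or duplicated SNP ids (first kept) are dropped and counted in
    ``df.attrs['drops']``. ``df.attrs['n_median']`` is the per-study sample
    size (median when N varies by SNP).
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep=r"\s+", dtype=str)
    df.columns = [c.upper() for c in df.columns]
    rename = {}
    for canon, names in _ALIASES.items():
        hit = [c for c in df.columns if c in names]
        if not hit:
            raise SchemaError(f"missing required column {canon!r} in {path}")
        rename[hit[0]] = canon
    df = df.rename(columns=rename)[list(_REQUIRED)]
    df.columns = ["snp", "a1", "a2", "z", "n"]

    n_in = len(df)
    df["z"] = pd.to_numeric(df["z"], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")
    df["a1"] = df["a1"].str.upper()
    df["a2"] = df["a2"].str.upper()

    drops = {}
    ok = np.isfinite(df["z"]) & np.isfinite(df["n"])
    drops["nonfinite_z_or_n"] = int((~ok).sum())
    df = df[ok]
    valid = (df["a1"].isin(VALID_ALLELES) & df["a2"].isin(VALID_ALLELES)
             & (df["a1"] != df["a2"]))
    drops["invalid_alleles"] = int((~valid).sum())
    df = df[valid]
    dup = df.duplicated("snp", keep="first")
    drops["duplicate_snp"] = int(dup.sum())
    df = df[~dup].reset_index(drop=True)

    df.attrs["drops"] = drops
    df.attrs["n_median"] = float(df["n"].median()) if len(df) else float("nan")
    if len(df) and df["n"].nunique() > 1:
        log.info("per-SNP N varies (%.0f-%.0f); using median %.0f",
                 df["n"].min(), df["n"].max(), df.attrs["n_median"])
    for k, v in drops.items():
        if v:
            log.info("read_sumstats(%s): dropped %d rows (%s)", path, v, k)
    log.info("read_sumstats(%s): %d of %d rows retained", path, len(df), n_in)
    return df


def is_ambiguous(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return ((a1 == "A") & (a2 == "T")) | ((a1 == "T") & (a2 == "A")) | \
           ((a1 == "C") & (a2 == "G")) | ((a1 == "G") & (a2 == "C"))


def qc_filter(df: pd.DataFrame, panel: pd.DataFrame, maf_min: float = 0.05,
              exclude_mhc: bool = True,
              mhc_window: tuple = DEFAULT_MHC) -> pd.DataFrame:
    """Restrict summary statistics to well-behaved panel SNPs.

    ``panel`` carries per-SNP reference metadata with columns
    (snp, chrom, pos, maf). Keeps autosomal (chrom 1-22), non-ambiguous
    SNPs with panel MAF >= ``maf_min``, outside the MHC window when
    ``exclude_mhc``. Adds chrom/pos columns from the panel.
    """
    merged = df.merge(panel[["snp", "chrom", "pos", "maf"]], on="snp",
                      how="inner")
    counts = {"not_in_panel": len(df) - len(merged)}

    chrom = pd.to_numeric(merged["chrom"], errors="coerce")
    keep = chrom.between(1, 22)
    counts["non_autosomal"] = int((~keep).sum())
    merged, chrom = merged[keep], chrom[keep]

    amb = is_ambiguous(merged["a1"], merged["a2"])
    counts["strand_ambiguous"] = int(amb.sum())
    merged, chrom = merged[~amb], chrom[~amb]

    rare = merged["maf"] < maf_min
    counts["low_maf"] = int(rare.sum())
    merged, chrom = merged[~rare], chrom[~rare]

    if exclude_mhc:
        c, lo, hi = mhc_window
        in_mhc = (chrom == c) & (merged["pos"] >= lo) & (merged["pos"] < hi)
        counts["mhc"] = int(in_mhc.sum())
        merged = merged[~in_mhc]

    merged = merged.reset_index(drop=True)
    merged.attrs.update(df.attrs)
    merged.attrs["qc_counts"] = counts
    if len(merged) == 0:
        log.warning("qc_filter: no SNPs survived QC (%s)", counts)
    return merged


def harmonize_pair(s1: pd.DataFrame, s2: pd.DataFrame) -> HarmonizedPair:
    """Align study 2 to study 1's effect alleles on the shared SNP set.

    Both inputs must already carry chrom/pos (i.e. be QC'd against the
    same panel). Where study 2's allele pair is the swap of study 1's,
    z2 is negated; SNPs whose pair matches neither orientation (allowing
    for a strand complement) are dropped and counted.
    """
    merged = s1.merge(s2[["snp", "a1", "a2", "z"]], on="snp",
                      suffixes=("", "_2"), how="inner")
    if merged.empty:
        raise ValueError(
            f"no SNPs shared between the two studies "
            f"({len(s1)} vs {len(s2)} after QC)")

    # both studies are assumed munged to a common strand (and
    # strand-ambiguous SNPs removed), so only the literal pair and its
    # swap are accepted; anything else is treated as a data error
    a1, a2 = merged["a1"], merged["a2"]
    b1, b2 = merged["a1_2"], merged["a2_2"]
    same = (a1 == b1) & (a2 == b2)
    swapped = (a1 == b2) & (a2 == b1)

    n_mismatch = int((~(same | swapped)).sum())
    merged = merged[same | swapped].copy()
    if merged.empty:
        raise ValueError(
            f"allele harmonization removed every shared SNP "
            f"({n_mismatch} mismatching pairs)")
    flip = swapped[same | swapped]
    merged["z2"] = np.where(flip, -merged["z_2"], merged["z_2"])
    merged = merged.rename(columns={"z": "z1"})

    out = merged[["snp", "chrom", "pos", "z1", "z2"]].copy()
    out["chrom"] = pd.to_numeric(out["chrom"]).astype(int)
    out["pos"] = pd.to_numeric(out["pos"]).astype(int)
    out = out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    counts = {"shared": len(out), "allele_mismatch": n_mismatch,
              "flipped": int(flip.sum())}
    log.info("harmonize_pair: %d shared SNPs, %d sign-flipped, %d dropped",
             len(out), counts["flipped"], n_mismatch)
    return HarmonizedPair(table=out,
                          n1=int(round(s1.attrs.get("n_median", np.nan))),
                          n2=int(round(s2.attrs.get("n_median", np.nan))),
                          counts=counts)


def read_partition(path) -> GenomePartition:
    """Read an LDetect-style 3-column partition (chr start stop)."""
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    if not {"chr", "start", "stop"}.issubset(df.columns):
        raise SchemaError(f"partition {path} must have columns chr start stop")
    out = pd.DataFrame({
        "chrom": pd.to_numeric(df["chr"].str.replace("chr", "", regex=False)),
        "start": pd.to_numeric(df["start"]).astype(int),
        "stop": pd.to_numeric(df["stop"]).astype(int),
    })
    return validate_partition(out)


def validate_partition(blocks: pd.DataFrame) -> GenomePartition:
    if (blocks["stop"] <= blocks["start"]).any():
        bad = blocks[blocks["stop"] <= blocks["start"]].iloc[0]
        raise ValueError(f"partition block with stop <= start: {dict(bad)}")
    blocks = blocks.sort_values(["chrom", "start"], kind="stable")
    blocks = blocks.reset_index(drop=True)
    prev = blocks.groupby("chrom")["stop"].shift()
    bad = prev.notna() & (blocks["start"] < prev)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"overlapping partition blocks on chrom "
            f"{blocks.loc[i, 'chrom']}: "
            f"{dict(blocks.loc[i - 1])} and {dict(blocks.loc[i])}")
    return GenomePartition(blocks=blocks)


def assign_to_blocks(pair: HarmonizedPair,
                     partition: GenomePartition) -> dict[int, np.ndarray]:
    """Map block index -> integer row indices of ``pair.table`` in the block.

    A SNP at position p belongs to block (c, start, stop) iff its
    chromosome is c and start <= p < stop. SNPs covered by no block are
    dropped (count recorded in ``pair.counts['outside_partition']``).
    """
    assignment: dict[int, np.ndarray] = {}
    n_assigned = 0
    tab = pair.table
    for i, blk in partition.blocks.iterrows():
        mask = ((tab["chrom"] == blk["chrom"])
                & (tab["pos"] >= blk["start"]) & (tab["pos"] < blk["stop"]))
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size:
            assignment[int(i)] = idx
            n_assigned += idx.size
    pair.counts["outside_partition"] = len(tab) - n_assigned
    return assignment
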