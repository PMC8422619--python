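"""End-to-end orchestration: files or arrays in, per-block estimates out.

Two entry points:

* :func:`analyze_arrays` — the computational core. Takes aligned z-score
  vectors, per-block eigensystems and genome-wide LD scores (all already
  harmonized to the same SNP order) and runs the intercept regression,
  every per-block estimate and, optionally, the pooled global estimate.
  The simulator calls this directly.

* :func:`analyze_files` — the tool path. Reads two summary-statistics
  files, a PLINK reference panel and a genome partition; QCs and
  harmonizes; builds the LD eigensystems and LD scores from the panel;
  then defers to :func:`analyze_arrays`. Produces a tidy results table
  and a run manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ld, local, plinkio, sumstats
from .global_cov import BlockWork, GlobalCovarianceEstimate, global_cov
from .intercept import CrossTraitIntercept, cross_trait_regression
from .local import LocalCovarianceEstimate, compute_eta, estimate_block

log = logging.getLogger(__name__)

RESULT_COLUMNS = ["chrom", "start", "stop", "m", "k", "rho", "var", "p",
                  "h2_1", "h2_2", "corr", "corr_se"]


@dataclass
class AnalysisResult:
    estimates: list[LocalCovarianceEstimate]
    intercept: CrossTraitIntercept
    blocks: list[BlockWork]
    global_estimate: GlobalCovarianceEstimate | None = None
    manifest: dict = field(default_factory=dict)

    def table(self, partition: pd.DataFrame | None = None) -> pd.DataFrame:
        rows = []
        for est in self.estimates:
            row = {"chrom": np.nan, "start": np.nan, "stop": np.nan,
                   "m": est.m, "k": est.k, "rho": est.rho,
                   "var": est.var_total, "p": est.p_value,
                   "h2_1": est.h2_1, "h2_2": est.h2_2,
                   "corr": est.corr, "corr_se": est.corr_se}
            if partition is not None:
                blk = partition.loc[est.block]
                row.update(chrom=blk["chrom"], start=blk["start"],
                           stop=blk["stop"])
            rows.append(row)
        return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def analyze_arrays(z1, z2, n1, n2, eigensystems, block_index, ld_scores,
                   k_min: int = local.DEFAULT_K_MIN, k_max: int | None = None,
                   do_global: bool = False,
                   intercept: CrossTraitIntercept | None = None,
                   weights: str = "ldsc",
                   n_jackknife_blocks: int | str = "auto") -> AnalysisResult:
    """Run the full estimator on pre-harmonized arrays.

    Parameters
    ----------
    z1, z2 : aligned z scores, genome order.
    eigensystems : dict block-id -> EigenSystem for every block with SNPs.
    block_index : dict block-id -> integer row indices into z1/z2.
    ld_scores : per-SNP LD scores aligned with z1/z2.
    k_max : rank cap; callers normally pass the reference-panel sample
        count so that no block uses more components than the panel can
        support.
    intercept : reuse a previously fitted overlap intercept (e.g. across
        simulation replicates over the same genotypes) instead of
        refitting.
    """
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    if intercept is None:
        # jackknife blocks aligned to LD-block boundaries so no block is
        # cut in half (a cut deflates the variance estimate)
        from .intercept import grouped_edges
        starts = [int(np.min(idx)) for idx in block_index.values() if len(idx)]
        edges = grouped_edges(starts, z1.size) if starts else None
        intercept = cross_trait_regression(
            z1, z2, n1, n2, ld_scores, weights=weights,
            n_jackknife_blocks=n_jackknife_blocks,
            jackknife_edges=edges)

    estimates: list[LocalCovarianceEstimate] = []
    works: list[BlockWork] = []
    for bid in sorted(block_index):
        idx = block_index[bid]
        eig = eigensystems[bid]
        z1_t = ld.transform_z(z1[idx], eig)
        z2_t = ld.transform_z(z2[idx], eig)
        var_a_df = intercept.n_blocks - 1 if intercept.n_blocks >= 2 else None
        est = estimate_block(z1_t, z2_t, eig.w, n1, n2, eig.m,
                             intercept.a_hat, intercept.var_a,
                             k_min=k_min, k_max=k_max, block=bid,
                             var_a_df=var_a_df)
        estimates.append(est)
        if est.status != "not_estimable":
            works.append(BlockWork(
                w=eig.w[:est.k], eta=compute_eta(z1_t[:est.k], z2_t[:est.k],
                                                 eig.w[:est.k],
                                                 intercept.a_hat),
                k=est.k, m=est.m, h2_1_raw=est.h2_1, h2_2_raw=est.h2_2))

    result = AnalysisResult(estimates=estimates, intercept=intercept,
                            blocks=works)
    if do_global:
        df = intercept.n_blocks - 1 if intercept.n_blocks >= 2 else None
        result.global_estimate = global_cov(works, n1, n2, intercept.var_a,
                                            var_a_df=df)
    return result


def analyze_files(sumstats1, sumstats2, bfile, partition_path,
                  n1: int | None = None, n2: int | None = None,
                  maf_min: float = 0.05, exclude_mhc: bool = True,
                  k_min: int = local.DEFAULT_K_MIN, k_max: int | None = None,
                  do_global: bool = False, ld_window_bp: int = 1_000_000,
                  weights: str = "ldsc") -> AnalysisResult:
    """File-based pipeline: sumstats pair + PLINK panel + partition."""
    s1 = sumstats.read_sumstats(sumstats1)
    s2 = sumstats.read_sumstats(sumstats2)
    partition = sumstats.read_partition(partition_path)

    dosages, bim, fam = plinkio.read_bed(str(bfile))
    panel_meta = pd.DataFrame({
        "snp": bim["snp"], "chrom": bim["chrom"], "pos": bim["pos"],
        "maf": plinkio.panel_maf(dosages),
    })
    q1 = sumstats.qc_filter(s1, panel_meta, maf_min=maf_min,
                            exclude_mhc=exclude_mhc)
    q2 = sumstats.qc_filter(s2, panel_meta, maf_min=maf_min,
                            exclude_mhc=exclude_mhc)
    pair = sumstats.harmonize_pair(q1, q2)
    if n1 is not None:
        pair.n1 = int(n1)
    if n2 is not None:
        pair.n2 = int(n2)

    # panel columns for the retained SNPs, in the pair's genome order
    col_of = pd.Series(np.arange(len(bim)), index=bim["snp"])
    panel_cols = col_of.loc[pair.table["snp"]].to_numpy()
    X = dosages[:, panel_cols]
    X, kept = ld.standardize_genotypes(X, return_index=True)
    if kept.size != len(pair.table):
        pair.table = pair.table.iloc[kept].reset_index(drop=True)
        pair.counts["monomorphic_in_panel"] = len(panel_cols) - kept.size
    n_ref = X.shape[0]
    if k_max is None:
        k_max = n_ref

    block_index = sumstats.assign_to_blocks(pair, partition)
    eigensystems = {}
    for bid, idx in block_index.items():
        eigensystems[bid] = ld.eigendecompose(ld.estimate_ld(X[:, idx]))
    scores = ld.compute_ld_scores(X, pair.table["pos"].to_numpy(),
                                  pair.table["chrom"].to_numpy(),
                                  window_bp=ld_window_bp)

    result = analyze_arrays(
        pair.table["z1"].to_numpy(), pair.table["z2"].to_numpy(),
        pair.n1, pair.n2, eigensystems, block_index, scores,
        k_min=k_min, k_max=k_max, do_global=do_global, weights=weights)

    status = {}
    for i in range(len(partition)):
        if i not in block_index:
            status[i] = "skipped:no_snps"
    for est in result.estimates:
        status[est.block] = est.status
    result.manifest = {
        "inputs": {"sumstats1": str(sumstats1), "sumstats2": str(sumstats2),
                   "bfile": str(bfile), "partition": str(partition_path)},
        "n1": pair.n1, "n2": pair.n2, "m": pair.m, "n_ref": n_ref,
        "qc": {"study1": q1.attrs.get("qc_counts"),
               "study2": q2.attrs.get("qc_counts"),
               "harmonization": pair.counts},
        "intercept": {"a_hat": result.intercept.a_hat,
                      "var_a": result.intercept.var_a,
                      "slope": result.intercept.slope},
        "block_status": {int(k): v for k, v in sorted(status.items())},
    }
    result.manifest["partition_table"] = partition.blocks
    return result


def write_results(result: AnalysisResult, path, partition=None) -> None:
    """Write the per-block results TSV (one row per block, genome order)."""
    partition = result.manifest.get("partition_table") if partition is None \
        else partition
    tab = result.table(partition)
    tab.to_csv(path, sep="\t", index=False, float_format="%.6e", na_rep="NA")
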