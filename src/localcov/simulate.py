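"""Forward simulator for bivariate GWAS pairs with LD, sample overlap and
local/global genetic covariance.

The generative model mirrors the estimator's assumptions. Within each LD
block, haplotypes follow a two-level architecture that emulates the
clumped LD of real genotype panels: SNPs come in *clumps* of tightly
linked markers (sizes log-uniform up to ``clump_size_max``, pairwise
haplotype correlation drawn from ``clump_r_range``, one shared allele
frequency per clump), and each clump's founder SNP follows a first-order
Markov chain across clumps with correlation drawn from
``founder_r_range``. Blocks are mutually independent. Setting
``clump_size_max = 1`` collapses the model to a plain first-order chain
whose adjacent-SNP correlation is the scalar ``ld_r`` (exact when
neighbouring allele frequencies permit it, clipped to the feasible range
otherwise). The clumped default matters: it produces the wide LD-score
spread and the well-separated LD eigenvalues that real panels have, on
which both the cross-trait intercept regression and the reference-panel
eigendecomposition depend.

Diploid dosages are haplotype sums; allele frequencies are drawn
uniformly from ``maf_range``. Two GWAS cohorts share their first ``n_s``
individuals, and an independent draw of ``n_ref`` individuals plays the
reference panel (same LD architecture, new samples).

Per-SNP effects (beta_j, gamma_j) are bivariate normal with variances
h2_t / m and covariance rho / m (global design: every SNP) or
rho_local / m_target inside the designated target block and 0 elsewhere
(local design). Phenotypes are phi = X beta + noise, with noise variance
1 - h2 and covariance rho_e between the two studies' noise on shared
individuals only; phenotypes are then centred and rescaled to unit
variance so the z-score approximation z_j = x_j' phi / sqrt(n) holds
exactly. The same master seed always reproduces the same panels and the
same replicate stream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import ld, pipeline

log = logging.getLogger(__name__)

#: default desk-scale genome: one 400-SNP target block plus eleven
#: 182-SNP background blocks (~2,400 SNPs)
DEFAULT_BLOCKS = (400,) + (182,) * 11


@dataclass
class SimulationConfig:
    """Generative parameters for one simulated study pair."""

    seed: int
    n1: int = 4000
    n2: int = 4000
    n_s: int = 0
    n_ref: int = 503
    block_sizes: tuple = DEFAULT_BLOCKS
    target_block: int = 0
    maf_range: tuple = (0.05, 0.5)
    ld_r: float = 0.5
    clump_size_max: int = 80
    clump_r_range: tuple = (0.95, 0.999)
    founder_r_range: tuple = (0.05, 0.5)
    h2_1: float = 0.5
    h2_2: float = 0.5
    rho_global: float = 0.0
    rho_local: float | None = None   # switches on the local design
    rho_e: float = 0.0
    snp_spacing_bp: int = 2500

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not 0 <= self.n_s <= min(self.n1, self.n2):
            raise ValueError("n_s must satisfy 0 <= n_s <= min(n1, n2)")
        if not 0.0 <= self.ld_r < 1.0:
            raise ValueError("ld_r must be in [0, 1)")
        if self.rho_e ** 2 > (1 - self.h2_1) * (1 - self.h2_2) + 1e-12:
            raise ValueError("rho_e exceeds the noise-variance bound")
        per_snp_cov = np.abs(self._per_snp_cov())
        bound = np.sqrt(self.h2_1 * self.h2_2) / self.m
        if np.any(per_snp_cov > bound + 1e-15):
            raise ValueError(
                "genetic covariance violates positive semidefiniteness of "
                "the per-SNP effect distribution")

    @property
    def m(self) -> int:
        return int(sum(self.block_sizes))

    @property
    def block_slices(self) -> list[slice]:
        edges = np.concatenate([[0], np.cumsum(self.block_sizes)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    def _per_snp_cov(self) -> np.ndarray:
        cov = np.full(self.m, self.rho_global / self.m)
        if self.rho_local is not None:
            cov[:] = 0.0
            sl = self.block_slices[self.target_block]
            cov[sl] = self.rho_local / self.block_sizes[self.target_block]
        return cov

    @property
    def true_rho_target(self) -> float:
        """True covariance of the evaluated quantity: the target block's
        local covariance in the local design, the genome total otherwise."""
        return float(self.rho_local if self.rho_local is not None
                     else self.rho_global)


@dataclass
class LDArchitecture:
    """One realization of the genome's LD structure, shared by the study
    cohorts and the reference panel."""

    p: np.ndarray          # per-SNP allele frequency
    clump_id: np.ndarray   # per-SNP clump index
    founders: np.ndarray   # per-clump founder SNP index
    r_member: np.ndarray   # per-SNP correlation to the clump founder (1 at founders)
    r_founder: np.ndarray  # per-clump chain correlation to the previous founder
                           # (0 at block starts)


def draw_ld_architecture(config: SimulationConfig, rng) -> LDArchitecture:
    """Draw clump boundaries, allele frequencies and correlation targets."""
    m = config.m
    p = np.empty(m)
    clump_id = np.empty(m, dtype=int)
    r_member = np.ones(m)
    founders, r_founder = [], []
    cid = -1
    for sl in config.block_slices:
        j = sl.start
        while j < sl.stop:
            if config.clump_size_max > 1:
                size = int(round(np.exp(
                    rng.uniform(0.0, np.log(config.clump_size_max)))))
            else:
                size = 1
            hi = min(j + max(size, 1), sl.stop)
            cid += 1
            clump_id[j:hi] = cid
            founders.append(j)
            p[j:hi] = rng.uniform(*config.maf_range)
            if hi > j + 1:
                r_member[j + 1:hi] = rng.uniform(*config.clump_r_range,
                                                 size=hi - j - 1)
            if j == sl.start:
                r_founder.append(0.0)
            elif config.clump_size_max > 1:
                r_founder.append(rng.uniform(*config.founder_r_range))
            else:
                r_founder.append(config.ld_r)
            j = hi
    return LDArchitecture(p=p, clump_id=clump_id,
                          founders=np.array(founders),
                          r_member=r_member,
                          r_founder=np.array(r_founder))


def _haplotypes(rng, n_hap: int, arch: LDArchitecture) -> np.ndarray:
    """Draw binary haplotypes for one sample set under a fixed architecture.

    Clump founders follow a first-order chain with target covariance
    r * sigma_prev * sigma_cur (transition probabilities clipped to [0, 1]
    when allele frequencies make the target infeasible); members are
    conditionally independent copies of their founder with correlation
    ``r_member`` (exact, since members share the founder's frequency).
    """
    p = arch.p
    m = p.size
    u = rng.random((n_hap, m))
    n_clump = arch.founders.size
    F = np.empty((n_hap, n_clump), dtype=np.uint8)
    for c in range(n_clump):
        jf = arch.founders[c]
        r = arch.r_founder[c]
        if r == 0.0:
            F[:, c] = u[:, jf] < p[jf]
        else:
            pp = p[arch.founders[c - 1]]
            pj = p[jf]
            sj = np.sqrt(pj * (1 - pj))
            a1 = min(pj + r * sj * np.sqrt((1 - pp) / pp), 1.0)
            a0 = max(pj - r * sj * np.sqrt(pp / (1 - pp)), 0.0)
            F[:, c] = u[:, jf] < np.where(F[:, c - 1] == 1, a1, a0)
    # members copy their founder: P(1|founder=1) = p + r(1-p), P(1|0) = p(1-r)
    a1 = p + arch.r_member * (1 - p)
    a0 = p * (1 - arch.r_member)
    Ff = F[:, arch.clump_id]
    H = (u < np.where(Ff == 1, a1[None, :], a0[None, :])).astype(np.uint8)
    H[:, arch.founders] = F
    return H


def simulate_genotypes(config: SimulationConfig) -> dict:
    """Draw the study cohorts and the reference panel.

    Returns dict with dosage matrices ``X1`` (n1 x m), ``X2`` (n2 x m) —
    whose first ``n_s`` rows are the same individuals — ``ref``
    (n_ref x m), the architecture and its allele frequencies.
    Deterministic in the config seed.
    """
    arch_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    arch = draw_ld_architecture(config, arch_rng)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    n_unique = config.n1 + config.n2 - config.n_s
    H = _haplotypes(rng, 2 * n_unique, arch)
    G = (H[0::2] + H[1::2]).astype(float)
    X1 = G[:config.n1]
    X2 = np.concatenate([G[:config.n_s], G[config.n1:]], axis=0)
    ref_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 3)))
    Href = _haplotypes(ref_rng, 2 * config.n_ref, arch)
    ref = (Href[0::2] + Href[1::2]).astype(float)
    return {"X1": X1, "X2": X2, "ref": ref, "mafs": arch.p, "arch": arch}


def draw_effects(config: SimulationConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP bivariate-normal effect sizes (beta, gamma)."""
    m = config.m
    vb = config.h2_1 / m
    vg = config.h2_2 / m
    cov = config._per_snp_cov()
    u1 = rng.standard_normal(m)
    u2 = rng.standard_normal(m)
    if vb > 0:
        beta = np.sqrt(vb) * u1
        resid = vg - cov ** 2 / vb
        if np.any(resid < -1e-15):
            raise ValueError("effect covariance matrix not positive semidefinite")
        # zero out cancellation dust so a degenerate (perfectly
        # correlated) draw is exactly proportional
        resid = np.where(resid < 1e-10 * max(vg, 1e-300), 0.0, resid)
        gamma = cov / np.sqrt(vb) * u1 + np.sqrt(resid) * u2
    else:
        if np.any(cov != 0):
            raise ValueError("nonzero covariance with zero heritability")
        beta = np.zeros(m)
        gamma = np.sqrt(vg) * u2
    return beta, gamma


def simulate_phenotypes(X1_std, X2_std, beta, gamma, config: SimulationConfig,
                        rng) -> tuple[np.ndarray, np.ndarray]:
    """phi = X beta + noise, correlated noise on shared samples, then
    centred and scaled to unit variance."""
    n1, n2, n_s = config.n1, config.n2, config.n_s
    v1 = 1.0 - config.h2_1
    v2 = 1.0 - config.h2_2
    eps = np.sqrt(v1) * rng.standard_normal(n1)
    delta = np.empty(n2)
    if n_s > 0 and v1 > 0:
        resid = v2 - config.rho_e ** 2 / v1
        delta[:n_s] = (config.rho_e / v1) * eps[:n_s] \
            + np.sqrt(max(resid, 0.0)) * rng.standard_normal(n_s)
    else:
        delta[:n_s] = np.sqrt(v2) * rng.standard_normal(n_s)
    delta[n_s:] = np.sqrt(v2) * rng.standard_normal(n2 - n_s)

    phi1 = X1_std @ beta + eps
    phi2 = X2_std @ gamma + delta
    phi1 = (phi1 - phi1.mean()) / phi1.std()
    phi2 = (phi2 - phi2.mean()) / phi2.std()
    return phi1, phi2


def run_gwas(X_std: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Marginal-association z scores z_j = x_j' phi / sqrt(n) on a
    standardized panel and a standardized phenotype."""
    n = X_std.shape[0]
    return (X_std.T @ phi) / np.sqrt(n)


class SimulatedWorld:
    """One genotype draw plus everything the estimator precomputes from it.

    Genotypes (both cohorts and the reference panel), the reference
    eigensystems and LD scores are fixed; replicates redraw effects and
    noise only — mirroring a study design where the same cohorts are
    phenotyped repeatedly.
    """

    def __init__(self, config: SimulationConfig):
        self.config = config
        g = simulate_genotypes(config)
        self.mafs = g["mafs"]
        self.X1 = ld.standardize_genotypes(g["X1"])
        self.X2 = ld.standardize_genotypes(g["X2"])
        self.ref_raw = g["ref"]
        ref = ld.standardize_genotypes(g["ref"])
        if self.X1.shape[1] != config.m or ref.shape[1] != config.m:
            # a monomorphic draw is possible in principle at tiny n; fail
            # loudly rather than silently misalign
            raise RuntimeError("monomorphic SNP in simulated panel; "
                               "increase sample size or MAF floor")
        self.positions = np.arange(config.m) * config.snp_spacing_bp + 1
        self.chroms = np.ones(config.m, dtype=int)
        self.block_index = {i: np.arange(sl.start, sl.stop)
                            for i, sl in enumerate(config.block_slices)}
        self.eigensystems = {
            i: ld.eigendecompose(ld.estimate_ld(ref[:, idx]))
            for i, idx in self.block_index.items()}
        self.ld_scores = ld.compute_ld_scores(ref, self.positions, self.chroms)

    def partition(self) -> pd.DataFrame:
        rows = []
        for i, sl in enumerate(self.config.block_slices):
            rows.append({"chrom": 1, "start": int(self.positions[sl.start]),
                         "stop": int(self.positions[sl.stop - 1]
                                     + self.config.snp_spacing_bp)})
        return pd.DataFrame(rows)

    def replicate(self, rep: int) -> tuple[np.ndarray, np.ndarray]:
        """z-score pair for replicate ``rep`` (counter-based stream from
        the master seed, so replicates are independent and reproducible
        in isolation)."""
        rng = np.random.default_rng(
            np.random.SeedSequence((self.config.seed, 1, rep)))
        beta, gamma = draw_effects(self.config, rng)
        phi1, phi2 = simulate_phenotypes(self.X1, self.X2, beta, gamma,
                                         self.config, rng)
        return run_gwas(self.X1, phi1), run_gwas(self.X2, phi2)

    def estimate(self, z1, z2, do_global: bool = False,
                 **kwargs) -> pipeline.AnalysisResult:
        cfg = self.config
        return pipeline.analyze_arrays(
            z1, z2, cfg.n1, cfg.n2, self.eigensystems, self.block_index,
            self.ld_scores, k_max=cfg.n_ref, do_global=do_global, **kwargs)


#: seed offset separating the genotype worlds of a multi-world experiment
WORLD_SEED_STRIDE = 7919


def replicate_experiment(config: SimulationConfig, n_reps: int,
                         alpha: float = 0.05,
                         world: SimulatedWorld | None = None,
                         worlds: list | None = None,
                         do_global: bool | None = None,
                         n_worlds: int = 1) -> dict:
    """Run the estimator over ``n_reps`` phenotype replicates.

    Evaluates the design's quantity of interest — the target block's
    local covariance in a local design, the genome-wide covariance in a
    global design — and summarizes calibration/accuracy: rejection
    proportion at ``alpha``, mean estimate, bias, RMSE, mean reported SE
    and the empirical SD of the estimates.

    With ``n_worlds > 1`` the replicates are spread over several
    independent genotype draws (seeds offset by ``WORLD_SEED_STRIDE``),
    so the summary is marginal over genotype worlds rather than
    conditional on a single panel draw; estimator behaviour conditional
    on one panel varies with the luck of the reference draw, and the
    marginal rate is the quantity a frequentist claim is about.
    """
    from dataclasses import replace

    if worlds is not None:
        # reuse existing genotype worlds under a new effect law; each
        # keeps its own seed so replicate streams stay distinct
        for w in worlds:
            if (w.config.n1, w.config.n2, w.config.n_s,
                    w.config.block_sizes) != (config.n1, config.n2,
                                              config.n_s, config.block_sizes):
                raise ValueError("world geometry does not match the config")
            w.config = replace(config, seed=w.config.seed)
    elif world is not None:
        world.config = replace(config, seed=world.config.seed)
        worlds = [world]
    elif n_worlds <= 1:
        worlds = [SimulatedWorld(config)]
    else:
        worlds = [SimulatedWorld(replace(
            config, seed=config.seed + WORLD_SEED_STRIDE * i))
            for i in range(n_worlds)]
    local_design = config.rho_local is not None
    if do_global is None:
        do_global = not local_design
    truth = config.true_rho_target

    rhos = np.empty(n_reps)
    ses = np.empty(n_reps)
    pvals = np.empty(n_reps)
    sums_local = np.empty(n_reps)
    for rep in range(n_reps):
        wld = worlds[rep % len(worlds)]
        z1, z2 = wld.replicate(rep)
        res = wld.estimate(z1, z2, do_global=do_global)
        if local_design:
            est = res.estimates[config.target_block]
            rhos[rep] = est.rho
            ses[rep] = np.sqrt(est.var_total)
            pvals[rep] = est.p_value
        else:
            g = res.global_estimate
            rhos[rep] = g.rho
            ses[rep] = np.sqrt(g.var)
            pvals[rep] = g.p_value
        sums_local[rep] = np.nansum([e.rho for e in res.estimates])

    bias = float(np.mean(rhos) - truth)
    return {
        "truth": truth,
        "n_reps": n_reps,
        "rejection_rate": float(np.mean(pvals < alpha)),
        "mean_estimate": float(np.mean(rhos)),
        "bias": bias,
        "rmse": float(np.sqrt(np.mean((rhos - truth) ** 2))),
        "mean_se": float(np.mean(ses)),
        "empirical_sd": float(np.std(rhos, ddof=1)),
        "mc_se_of_mean": float(np.std(rhos, ddof=1) / np.sqrt(n_reps)),
        "estimates": rhos,
        "p_values": pvals,
        "sum_local": sums_local,
    }


# ---------------------------------------------------------------------------
# on-disk study pairs (for the command-line workflow)


def write_study_pair(world: SimulatedWorld, rep: int, outdir) -> dict:
    """Write one replicate as files: reference panel (PLINK triplet),
    two summary-statistics TSVs, the partition, and a truth record."""
    import pathlib

    from . import plinkio

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = world.config
    m = cfg.m
    snp = [f"rs{i + 1}" for i in range(m)]
    bim = pd.DataFrame({
        "chrom": world.chroms, "snp": snp, "cm": 0.0,
        "pos": world.positions, "a1": "A", "a2": "G"})
    plinkio.write_bed(str(outdir / "panel"), world.ref_raw, bim)

    z1, z2 = world.replicate(rep)
    for name, z, n in (("sumstats1.txt", z1, cfg.n1),
                       ("sumstats2.txt", z2, cfg.n2)):
        pd.DataFrame({"SNP": snp, "A1": "A", "A2": "G", "Z": z, "N": n}) \
            .to_csv(outdir / name, sep="\t", index=False)

    part = world.partition()
    part = part.rename(columns={"chrom": "chr"})
    part["chr"] = "chr" + part["chr"].astype(str)
    part.to_csv(outdir / "partition.txt", sep="\t", index=False,
                columns=["chr", "start", "stop"])

    truth = asdict(cfg)
    truth["true_rho_target"] = cfg.true_rho_target
    truth["replicate"] = rep
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=lambda o: list(o))
    return truth
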