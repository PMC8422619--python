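# Methods

## Statistical model

Two GWAS with sample sizes n₁, n₂ measure standardized traits
φ₁ = Xβ + ε and φ₂ = Yγ + δ on standardized genotype matrices. Effects
are random: per SNP j, (β_j, γ_j) is bivariate normal with variances
h²₁/m, h²₂/m and covariance ρ/m (genome-wide) or, in the local model,
covariance ρ_i/m_i for SNPs in region i and 0 elsewhere, where m_i is
the region's SNP count — so ρ_i is the region's total genetic
covariance. The first n_s individuals are shared between the studies and
their non-genetic residuals have covariance ρ_e; ρ_t denotes the total
trait covariance on shared samples.

Writing z₁, z₂ for the marginal z-scores (z₁j ≈ X'_{·j}φ₁/√n₁) and V_i
for region i's LD matrix with eigendecomposition V_i = U_i Σ_i U_iᵀ,
Σ_i = diag(w_i1 ≥ … ≥ w_im_i), the decorrelated scores z̃ = U_iᵀz satisfy

    E[z̃₁ij z̃₂ij]  = (√(n₁n₂) ρ_i / m_i) w_ij² + a w_ij
    Var[z̃₁ij z̃₂ij] ≈ q_ij² = (n₁h²₁i/m_i · w_ij² + w_ij)(n₂h²₂i/m_i · w_ij² + w_ij)

with a = n_s ρ_t / √(n₁n₂) the overlap nuisance.

## Estimation pipeline

**Overlap intercept.** a is estimated genome-wide as the free intercept
of the weighted regression of z₁j z₂j on √(n₁n₂)·ℓ_j/m (ℓ_j = LD score
from the reference panel, 1-Mb window, unbiased r² adjustment
r²−(1−r²)/(n_ref−2)). Weights are two-step: univariate first passes
z_t² ~ n_t ℓ/m give crude polygenicity slopes c_t, and the cross pass
uses 1/[max(ℓ,1)(1+c₁ℓ)(1+c₂ℓ)] — the reciprocal of the approximate
product variance. Var(â) comes from a delete-one block jackknife whose
blocks are aligned to LD-block boundaries and sized ≥ ~200 SNPs (at most
200 blocks): a jackknife block narrower than the LD correlation length
deflates the variance estimate, which at desk scale is a factor-two
effect. The intercept is never constrained to zero, even when the user
believes the studies are disjoint.

**Per-block estimate.** With η_ij = z̃₁ij z̃₂ij − â·w_ij, the estimate is
the no-intercept weighted least squares slope of η on w², rescaled:

    ρ̂_i = (m_i/√(n₁n₂)) · Σ_{j≤K} η_ij w_ij²/q_ij² / Σ_{j≤K} w_ij⁴/q_ij²

Its variance given â has an analytic (information) form
(m_i²/(n₁n₂)) / Σ w⁴/q² and a residual-based form — the same quantity
times the weighted residual sum of squares over (K−1). The uncertainty
of â propagates with the exact derivative dρ̂/dâ:
(m_i²/(n₁n₂))·(Σw³/q² / Σw⁴/q²)²·Var(â). Total variance is the sum of
the residual-based and propagated terms (law of total variance).

**Adaptive rank K_i.** Reference panels are small (503 samples by
default), so only the leading eigencomponents of V̂_i are trustworthy.
For every K from 10 (or m_i, if smaller) to min(m_i, n_ref), both
variance forms are computed — heritabilities re-estimated from the
truncated spectrum at each K, which also keeps the search from running
into the numerical-rank tail where components are pure noise — and K_i
minimizes v(K) = max(analytic, residual-based), smallest K on ties.

**Inference.** The test statistic is ρ̂_i/√(var). Because the residual
variance carries K−1 degrees of freedom and Var(â) only B−1 (jackknife
blocks), the p value uses a t reference with Welch–Satterthwaite
effective df; with genome-scale inputs (B = 200, K ~ 500) this is the
normal reference. The variance entering the statistic guards the
residual-based term with its analytic floor at the selected K: the rank
search minimizes max(analytic, residual), so the residual term evaluated
at the argmin is biased low by selection. The reported variance fields
keep the plain residual/propagated decomposition.

**Heritability, correlation, scales.** Local h²'s are method-of-moments:
ĥ² = m_i(Σ_{j≤K} z̃²_j/w_j − K)/(n Σ_{j≤K} w_j), derived by moment-matching
E[z̃_j²] = (n h²/m_i)w_j² + w_j on the truncated spectrum; raw values may
be negative and are clipped at zero only inside the weights. Local
correlation ρ̂_i/√(ĥ²₁iĥ²₂i) gets a first-order delta-method SE treating
the three estimates as independent; it is reported as undefined when
either heritability is non-positive (the ratio is then unstable —
covariance, not correlation, is the primary inference surface).
Case-control (observed-scale) covariances convert to the liability scale
by dividing by φ(τ₁)φ(τ₂)√(P₁(1−P₁)P₂(1−P₂))/[K₁(1−K₁)K₂(1−K₂)], a
positive constant, so significance and sign are scale-invariant.

**Global mode.** The genome-wide LD matrix is block diagonal, so the
genome is one big region: all blocks' retained components are pooled
into a single no-intercept WLS with weights built from genome-wide
heritabilities (sum of clipped per-block estimates) and per-SNP
covariance ρ/m_total. Per-block K_i are reused. The sum of local
estimates and the global estimate should agree closely; the package
reports that concordance.

## Synthetic data generator

The simulator emulates the three inputs end to end: genotype cohorts
(with the first n_s individuals shared), a separate reference panel
drawn from the same population, and marginal z-scores computed exactly
as z = X'φ/√n on standardized genotypes and unit-variance phenotypes
(phenotypes are divided by their realized SD so the z-score
approximation holds exactly).

**LD architecture.** Haplotypes follow a two-level model per block:
SNPs come in clumps (sizes log-uniform on 1..`clump_size_max`, default
80) that share one allele frequency (uniform on `maf_range`, default
0.05–0.5); each clump member copies its founder haplotype with
correlation drawn from `clump_r_range` (default 0.95–0.999), and
founders form a first-order Markov chain across clumps with correlation
from `founder_r_range` (default 0.05–0.5). Blocks are independent.
This produces the two features of real panels the estimator depends on:
a wide LD-score distribution (~1–75 here), without which the intercept
and slope of the LD score regression are not separable, and a decaying,
well-separated LD eigen-spectrum, without which a 503-sample reference
cannot estimate the leading eigenvectors and the estimator attenuates.
A homogeneous first-order chain (available as `clump_size_max=1` with
adjacent correlation `ld_r`, exact for equal allele frequencies) fails
both requirements and is kept only as a degenerate special case for
generator verification.

**Effects, noise, overlap.** Per-SNP effect pairs are exact bivariate
normal draws with the model covariances (a degenerate, perfectly
correlated draw yields exactly proportional effects). Noise is bivariate
normal with covariance ρ_e on shared individuals and independent
elsewhere, variances 1−h². Defaults follow the validated study
conditions: m ≈ 2,400 SNPs in 12 blocks (one 400-SNP target block),
n₁ = n₂ = 4,000, n_ref = 503, h² = 0.5 per trait spread evenly over all
SNPs, local grid ρ_i ∈ {0, 0.001, …, 0.005}, global grid
ρ ∈ {0, 0.05, …, 0.25}, shared-noise covariance 0.2 in overlap
scenarios, overlap fractions {0, 50%, 100%}.

**Reproducibility.** All randomness flows from one integer seed; the LD
architecture, cohort and reference draws, and each replicate's effects
and noise use separate counter-based streams (`SeedSequence((seed,
stream, replicate))`), so any replicate is reproducible in isolation and
identical seeds give bit-identical outputs. Multi-world experiments
offset seeds by a fixed stride.

## What the simulations do and do not show

Replicate experiments report type-I error/power (rejection fraction at
0.05), bias, RMSE, and reported-SE versus empirical-SD. Experiments can
be run conditional on one genotype draw or marginal over several
(`n_worlds`); calibration conditional on a single reference draw varies
with the luck of that draw (rejection 0.04–0.075 across worlds at desk
scale), so headline calibration claims are made marginally over 10
worlds. At desk scale two small biases remain and are visible in the
validation runs: the genome-wide intercept absorbs part of a
concentrated local signal (≈ −0.0015 at ρ_i = 0.005, because the target
block is ~17% of the miniature genome), and the global estimate is
attenuated 2–6% relative through the same slope/intercept coupling.
Both shrink with genome size and are within the validation tolerances.
The generator draws idealized bivariate-normal effects and Gaussian
noise on a homogeneous population; it does not emulate stratification,
assortative mating, MAF-dependent architecture, imputation error, or
case-control ascertainment (liability conversion is analytic only), so
passing tests certify the estimator under its own model assumptions,
not robustness to those violations.

## Numerical choices and edge cases

* LD divisor is n_ref (not n_ref−1), so trace(V̂) = m_i exactly.
* Eigenvalues are clipped at zero; components below 1e-8 of the top
  eigenvalue count as numerical rank deficiency and are never used.
* Missing reference genotypes are mean-imputed per SNP; monomorphic
  columns are dropped (counted in the manifest).
* Blocks with m_i below the K lower bound use all their components; the
  residual variance needs K ≥ 3, otherwise the analytic form stands in.
* Empirical residual sums are clipped at zero against cancellation
  (Cauchy–Schwarz guarantees non-negativity in exact arithmetic).
* MHC exclusion window: chromosome 6, [25, 35) Mb, configurable;
  strand-ambiguous = {A,T} or {C,G}; blocks are half-open [start, stop);
  per-study N is the file's median when it varies by SNP; duplicate SNP
  ids keep the first occurrence. Study-2 alleles matching study-1's pair
  in swapped order flip the z sign; any other pair is dropped (inputs
  are assumed munged to a common strand).
* Results TSV uses scientific notation with 6 significant digits and NA
  for undefined correlations.

## Known limitations

Local correlation estimates inherit the instability of local
heritability denominators. The intercept's variance dominates per-block
uncertainty when the genome (or its miniature) is short, and the
t-reference correction matters exactly there. Annotation-stratified
covariance, empirical-Bayes summaries of the fraction of correlated
regions, in-sample LD, and build liftover are out of scope.
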