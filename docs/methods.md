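# Methods

`bonesite` re-implements, end to end on synthetic data, the statistical
pipeline of a two-cohort genome-wide study of paediatric bone mineral
density (BMD) measured at four skeletal sites — total body less head
(TBLH), lower limb (LL), upper limb (UL) and skull (SK). Individual-level
data of the original cohorts are access-controlled, so every stage is
exercised on cohorts drawn from an explicit generating model, and the
published summary tables are used as recomputation inputs where the
derived quantities are exactly recomputable.

## Generating model (synthgen)

Genotypes. Each SNP receives an effect-allele frequency uniform on a
configurable range (default 0.05–0.5); hard genotypes are Binomial(2, p)
(Hardy–Weinberg proportions), with optional Gaussian dosage jitter
(default sd 0, i.e. hard calls) clipped to [0, 2] to emulate imputation
uncertainty. There is no linkage disequilibrium between panel SNPs; where
an analysis needs an LD partner, `correlated_snp` builds one by copying
an existing SNP's genotype per individual with probability ρ (expected
Pearson correlation ρ). Allele labels come from a stream keyed by
`allele_seed`, shared across cohorts by default so that two cohorts
simulate the same SNP map and remain mergeable in meta-analysis.

Phenotypes. For trait t with SNP-heritability h²_t and m_c causal SNPs,
per-SNP standardized effect 4-vectors are multivariate normal with
correlation R_g and per-trait variance h²_t/m_c; genetic values are the
standardized genotypes weighted by these vectors, residuals are
multivariate normal with correlation R_e and variance 1 − h²_t, so every
trait has unit variance before covariates. R_g and R_e are therefore
*generating parameters*, which makes their recovery by bivariate REML a
well-posed test. Passing one `effects_seed` to several cohorts gives
them a common causal architecture (same causal SNPs, same effects), as
cohorts measuring the same traits would have; without it each cohort
draws its own effects and meta-analysis shows gross heterogeneity.

Defaults. h² = (0.45, 0.40, 0.39, 0.51) for (TBLH, LL, UL, SK); the
published pairwise estimates fix four of the six correlations per matrix
(LL/UL r_g = 0.78, r_e = 0.55; SK vs TBLH/LL/UL r_g = 0.52/0.44/0.58,
r_e = 0.29/0.20/0.24). The TBLH rows against its limb components are not
published; as TBLH is a composite of the limb regions, they were set
once to r_g = (0.93, 0.90) and r_e = (0.85, 0.80) for (LL, UL), checked
for positive-definiteness, and not revisited. TBLH h² (also unpublished)
sits between the limb and skull values. Covariates, when enabled: age
uniform on a one-year clinic window around 9 y, sex Bernoulli(0.5),
weight/height correlated normals (r = 0.7) on child scales (kg, cm);
default loadings put roughly a quarter to a third of raw trait variance
on body size, mirroring how strongly DXA BMD tracks weight and height in
children.

Genotype QC retains SNPs with MAF ≥ 1%, call rate ≥ 95% and
Hardy–Weinberg exact P > 5×10⁻⁷. The HWE test enumerates heterozygote
counts conditional on the allele counts and sums the probabilities of
configurations no more probable than the observed one (ties included in
the tail, no mid-P), matching the common PLINK convention.

## Association and genomic control (assoc)

Traits are residualized on age, sex and weight (height replacing weight
for the skull, whose DXA measurement is adjusted for skeletal size
rather than loading), standardized to mean 0 / sd 1, and each SNP tested
by OLS of the standardized residual on its expected allelic dosage, with
optional ancestry principal components as covariates — the two-stage
(residualize-then-regress) convention, kept deliberately rather than a
joint covariate fit. Betas are in adjusted SD per effect-allele copy.
P-values use the normal (Wald) approximation, appropriate at n in the
thousands; a `use_t` switch restores the exact t reference. The genome
scan computes the identical estimator via Frisch–Waugh projection so a
whole panel is one matrix product. λ_GC is the median association χ²
over 0.45494 (the χ²₁ median), computed over all analysed SNPs;
correction multiplies SEs by √λ only when λ > 1, per cohort before
meta-analysis.

## Meta-analysis (metamod)

Cohort records are harmonized to a common effect allele (sign and
frequency flips for swapped alleles, strand complementation otherwise;
A/T and C/G SNPs are dropped when the smaller cohort MAF exceeds 0.40,
a configurable convention). Fixed-effects combination is inverse
variance: β̂ = Σwᵢβᵢ/Σwᵢ, w = SE⁻², SE = (Σw)^(−1/2). Heterogeneity is
Cochran's Q = Σwᵢ(βᵢ−β̂)² with I² = max(0, (Q−df)/Q)·100. Pooled EAF is
sample-size weighted. Genome-wide significance is strict P < 5×10⁻⁸.
Deep tails use `chdtrc`/log-space survival functions, accurate to the
10⁻⁴⁰ regime the reference tables require.

## Site-specificity test (sitespec)

For one SNP and the three-site score matrix Y (LL, UL, SK standardized),
the saturated trivariate-normal model has per-site intercepts and
slopes; equation-by-equation OLS is its ML mean estimator and Σ̂ the
1/n residual cross-product. Constrained fits (one shared slope, or one
freed site and a slope shared by the other two) use iterated feasible
GLS: given Σ, solve the GLS normal equations; given the means, update Σ
by ML; iterate to a log-likelihood change < 10⁻⁸ (max 200 iterations;
the trace is non-decreasing and asserted so in tests). Σ is re-estimated
under each constraint (joint ML); fixing it from the saturated model is
the noted alternative. The freed site maximizes |β̂_t − mean(β̂_u, β̂_v)|
from the saturated estimates, ties resolving to the fixed order
(LL, UL, SK); selection is made per cohort independently, with a flag to
pin it globally. The LRT statistic 2Δℓ is referred to χ²₁ and per-cohort
P-values are combined as Fisher's product (−2Σlog p on 2k df), judged at
α = 5×10⁻⁸.

Measured null behaviour: with the freed site *fixed*, the LRT is
calibrated (empirical rate 0.060 at the 0.05 level, n = 400). Choosing
the most different site from the same data makes the test the maximum of
three one-degree statistics whose underlying contrasts sum to zero
(pairwise correlation −1/2); the empirical rate is then ≈ 0.12,
essentially independent of the trait correlation structure. This
inflation is a property of the published procedure itself; it is
documented here and absorbed in practice by the very conservative α,
not corrected by adjusting the reference distribution.

## Conditional analysis (condmod)

Conditioning is individual-level: the target's regression is refit with
the conditioning dosages as covariates (conditioning SNPs in |r| ≥ 0.999
with the target raise a collinearity error naming the SNP), and the
conditional estimates are meta-analysed as usual. Locus significance
thresholds use Nyholt's spectral decomposition: with eigenvalues λ of
the locus LD correlation matrix, Var_obs = Σ(λᵢ−1)²/(M−1) and
Meff = 1 + (M−1)(1 − Var_obs/M); the locus alpha is 0.05/Meff and a
secondary signal is declared when the conditional meta P ≤ that
threshold (≤, not <). The original Nyholt form is used; the Li–Ji
variant is not.

## Variance components (greml)

The genetic relationship matrix is the standard allele-frequency
standardized estimator A_jk = (1/m)Σᵢ(x_ij−2pᵢ)(x_ik−2pᵢ)/(2pᵢ(1−pᵢ)),
with the same formula on and off the diagonal (the inbreeding-adjusted
diagonal variant is omitted; negligible at these scales). Relatedness
pruning is greedy: while any pair exceeds the cutoff (default 0.025),
remove the individual in the most offending pairs, later id on ties.

Univariate REML for y ~ N(μ1, σ²_g A + σ²_e I) rotates into the
eigenbasis of A (ridge 10⁻⁶ for numerical positive-definiteness) and
profiles the restricted likelihood over h = σ²_g/(σ²_g+σ²_e) by bounded
1-D optimization — exact for a single-GRM model. The SE of h comes from
the finite-difference observed information of (σ²_g, σ²_e) by the delta
method; the σ²_g = 0 test uses the 50:50 χ²₀/χ²₁ boundary mixture.

Bivariate REML fits vec(Y) ~ N(Xb, G⊗A + E⊗I) (G, E the 2×2 genetic and
residual covariance matrices) by average-information updates. In the
eigenbasis the 2n×2n covariance splits into n independent 2×2 blocks
dᵢG + E, so the restricted likelihood, scores and AI terms all cost
O(n) per iteration. Start values split each trait's variance equally
between components with zero covariances; steps are accepted only if
they keep every block positive definite, the component matrices
numerically PSD, and the log-likelihood non-decreasing (step-halving,
with a pseudo-inverse AI solve, a score-direction fallback and
single-coordinate moves for constrained ridges). Convergence is a
log-likelihood change < 10⁻⁶ on an untruncated step. Degenerate inputs
(e.g. a duplicated trait, whose likelihood is unbounded at the
singular boundary) terminate at the feasibility boundary with the
correlation estimates clipped to [−1, 1] and flagged. r_g = 0 is tested
by refitting with c_g fixed at zero (plain χ²₁, interior hypothesis);
SEs of r_g and r_e come from the inverse AI matrix by the delta method.

## Problem sizes and what the tests show

The replicated recovery studies use 10 cohorts of n = 2,000 individuals
by m = 5,000 SNPs with every SNP causal — the design in which GREML's
assumed architecture matches the generator exactly, so the means over
replicates estimate the generating values without model error; the
per-replicate sampling sd is ≈ 0.05 on a correlation. The demo pipeline
runs two cohorts of 1,000 and 800 by 2,000 SNPs with a 1% causal
background, which keeps λ_GC in the 1.01–1.03 regime of a
well-controlled polygenic GWAS. Null-calibration suites use 2,000
replicates at n = 400 (site-specificity LRT) and 10⁶ statistics (λ_GC).

Because the generator has no LD, no population stratification beyond
the two-subpopulation PCA test fixture, no missing phenotypes and
Gaussian traits, passing tests validate the estimators and their
numerics — not robustness to stratification, imputation error or
non-normality in real cohorts. The synthetic cohorts emulate the study's
sample sizes and correlation structure, not its genomes: positions are
arbitrary, panels are small, and no real loci exist to rediscover.

## Known limitations

- Nyholt's Meff is not additive over LD blocks; only closed-form cases
  are asserted.
- The data-driven site selection makes the nominal χ²₁ reference
  anti-conservative (~2.4× at the 0.05 level; see above).
- Printed reference rows recombine to the printed meta values within
  one unit of the last printed digit; one row (TBLH rs754388) cannot
  round-trip to half a unit because the printed three-decimal cohort
  inputs already carry rounding error.
- AI-REML SEs are asymptotic (inverse average information); no
  small-sample correction is applied.
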