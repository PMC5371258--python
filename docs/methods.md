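# Methods

`snpherit` implements a genomic analysis workflow for a quantitative
trait in a family-structured population: SNP quality control, additive
and dominance genomic relationship matrices, GREML variance components
with GBLUP prediction, single-SNP association scans with stratification
control, tenfold validation with three accuracy measures, and a
framework for quantifying what a named set of SNPs contributes to the
genomic heritability and to prediction accuracy. A synthetic-data
generator with known truth backs every stage's tests.

## Mixed model

The core model is

    y = X_b b + Z a + Z d + e,
    Var(y) = V = Z A_g Z' s2_a + Z D_g Z' s2_d + I s2_e,

with batch (year-month) fixed effects in `X_b`, genomic breeding values
`a`, dominance deviations `d` and residual `e`. The relationship
matrices are built from the sample allele frequencies:

    A_g = W_a W_a' / sum_k 2 p_k q_k,        W_a[i,k] = x_ik - 2 p_k
    D_g = W_d W_d' / sum_k (2 p_k q_k)^2,    W_d in {-2q^2, 2pq, -2p^2}

for alt-allele counts x in {0,1,2}. Heritabilities are ratios of
components to s2_y = s2_a + s2_d + s2_e (the model-based phenotypic
variance, not the raw sample variance), with broad-sense
h2_t = h2_a + h2_d. Delta-method standard errors come from the inverse
average-information matrix.

### REML algorithm

Average-information REML with an EM fallback. Each iteration factorizes
V once (dense Cholesky), forms the projection matrix P, takes the AI
step, and projects any component an AI step would push below
1e-6 * s2_y onto that boundary; if the AI matrix is singular or 100
iterations pass without convergence, the update falls back to EM.
Convergence requires the relative change of every free component below
1e-8 (boundary-pinned components count as settled) or a stagnant
restricted log-likelihood after iteration 10. Non-convergence after 200
iterations raises an error carrying the full trajectory. This dense
formulation is exact and adequate for the few-thousand-sample designs
the package targets; it is O(n^3) per iteration.

### GBLUP and reliability

Predictions use the covariance form a_hat = s2_a A[:,t] V_t^{-1}
(y_t - X_t b_hat) over the training records t, which also serves
individuals whose phenotypes are masked in validation. Reliability is
defined through the prediction-error variance,
rel_i = 1 - PEV_i / (K_ii s2), with K = A_g, D_g, or
s2_a A_g + s2_d D_g for the total genetic value. SNPs fitted as fixed
effects (the reduced model of the contribution analysis) enter `X` as
allele-count covariates; a 2-df genotypic coding (allele count plus a
heterozygote indicator) is available by flag.

### Per-SNP effects and heritabilities

Marker effects are back-solved from the GBLUP solutions,
alpha = s2_a W_a' V^{-1}(y - X b_hat) / sum 2pq, which reconstructs
W_a alpha = a_hat exactly. Raw per-SNP variances
Var_i(W_a[:,k] alpha_k) understate the additive component badly — BLUP
shrinkage alone bounds their sum by roughly n/m of it, and LD spreads
each QTL's signal across correlated markers whose cross-terms the
per-SNP sum ignores. They are therefore used as weights, normalized so
the per-SNP heritabilities decompose the REML component estimate
exactly (sum_k h2_k = h2_a). This reproduces the two empirical
signatures the package tests: per-SNP heritability scales as ~1/m with
panel size (halving the panel roughly doubles it), and the per-SNP sum
equals the total.

## Association scans

Three single-SNP methods:

- **GLS with family effects**: y = X_b b + X g + Z f + e, where f is a
  random family effect with common variance for sibs in a family
  ("family" defaults to litter, i.e. full sibs; sire grouping by flag).
  (s2_f, s2_e) are REML-estimated once under the no-SNP model and held
  fixed across the scan; each SNP is then fitted by whitened least
  squares using the analytic per-family block inverse square root of V.
- **LS, additive**: allele-count regression with the leading MDS
  coordinates of the identity-by-state distance matrix (PLINK
  convention, distance 1 - IBS) plus batch as covariates.
- **LS, genotypic**: the same covariates with a 3-level genotype
  factor.

Factor-model scans estimate the genotype-class values and t-test the
additive contrast a = (mu_AA - mu_aa)/2 and the dominance contrast
d = mu_Aa - (mu_AA + mu_aa)/2 with df = n - rank(fixed design). A
genotype class with fewer than 5 observations downgrades that SNP to
the allele-count regression (flagged `additive_only`). The genomic
inflation factor is median(t^2)/0.4549; the family-wise threshold is
Bonferroni alpha/m.

## Validation

`make_folds` partitions n individuals into k folds of floor(n/k) with
the remainder in the last fold (n=2936, k=10 gives 293x9 + 299).
Variance components are re-estimated within every training fold — the
source analysis is silent on this, and refitting avoids information
leakage. Three measures per genetic-effect type j in {a, d, t}:
observed phenotypic accuracy corr(g_hat_0j, y_0) with raw phenotypes
(an option pre-adjusts y_0 for fixed effects), expected genetic
accuracy R_0j = mean sqrt(reliability), and expected phenotypic
accuracy R_0jp = R_0j sqrt(h2_j) <= R_0j. Pooling is the mean across
folds with the SD across folds as the reported spread.

## Contribution of a SNP set

- **Method I** sums the per-SNP heritabilities of the set under the
  full model; it inherits the ~1/m dependency and is emitted with that
  caveat and no accuracy value.
- **Method II** rebuilds the GRMs without the set and refits; markers
  in LD with the removed set absorb part of its signal, so the drop is
  a lower bound. In family data the GRM also keeps capturing variance
  through kinship itself, which makes Method II conservative even at
  low LD.
- **Method III** ("partial heritability"/"partial accuracy") keeps all
  SNPs in the GRMs and fits the set as fixed covariates; the fixed SNPs
  also absorb the signal of correlated markers, so the drop is an upper
  bound. In cross-validation the fixed effects are estimated in each
  training fold and reach validation individuals through their
  genotypes.

Contributions are reported as c = 1 - reduced/full for each
heritability component and accuracy measure (the conventional tables
print decreases with a minus sign). For region sets, `chr:start-end`
strings resolve against SNP positions (1-based, inclusive).

## Synthetic data generator

The generator emulates a nucleus-herd paternal half-sib design: by
default 79 sires, 1456 litters (one unique dam each — dam structure is
not documented for the motivating population, so repeated dams are not
modelled) of 1-3 offspring, 24 year-month batches, ~41k autosomal SNPs
with MAF in (0.05, 0.5), and an integer trait calibrated to mean 10.72,
SD 1.72 with h2_a = 0.365 and h2_d = 0.035.

Founder haplotypes follow a first-order Markov chain per chromosome: a
latent Gaussian AR(1) with correlation `ld_decay` thresholded at each
marker's allele frequency. Offspring are produced by gene dropping with
recombination probability 1/(markers per chromosome) per
adjacent-marker interval (about one Morgan per chromosome). QTL are a
random subset of panel SNPs; additive effects are Gaussian, dominance
deviations use the statistical orthogonal coding at each QTL's
frequency, and both are rescaled on the *realized* sample variances so
small-sample recovery tests are exactly calibrated. Batch effects are
drawn once per level with SD `batch_sd` (phenotypic-SD units, default
0.1). Rounding to integers (default on) adds about 1/12 to the variance,
which keeps the sample SD within the calibration band.

What the generator does not emulate: genotyping error and missingness
(genotypes are complete; mean-imputation paths are exercised only via
user-supplied files), realistic site-frequency spectra, varying LD
along the chromosome, and multilocus LD. Passing tests therefore
demonstrate correctness of the estimators under a well-specified
polygenic additive+dominance model, not robustness to real GBS
artifacts.

## Problem sizes used by the test suite

The default suite exercises the estimators at sizes chosen to keep the
whole run in a few minutes while leaving the statistical properties
identifiable: parameter recovery at n=2000 individuals x m=2000 SNPs
with 200 QTL over 10 seeds; the panel-halving property at the full
study design (79 sires, 1456 litters, n around 2900) with a 1900-marker
panel at ld_decay 0.995, with causal variants excluded from the panel
so both half-panels tag them symmetrically (the GBS regime); null
calibration on 2000 null SNPs at n=800; everything else at n of a few
hundred. Grid/oracle equivalence checks run at n <= 60 where dense
brute force is exact.

## Numerical choices and edge cases

- GRM of an all-monomorphic panel raises a degenerate-input error;
  singular training V gets one automatic 1e-8 ridge with a warning.
- Rank-deficient fixed designs (e.g. a batch level entirely inside a
  masked validation fold, or collinear fixed SNPs) are reduced to a
  maximal independent column set by pivoted QR; dropped columns keep a
  zero coefficient so downstream indexing is stable.
- The two-locus EM for D' resolves only the double-heterozygote
  ambiguity, tolerance 1e-10, at most 1000 iterations; non-convergence
  raises an error carrying the last estimate. D_max follows Lewontin.
- HWE is the 1-df Pearson chi-square (an exact mid-p variant is
  provided); monomorphic SNPs get p = 1. The MAF filter is strict
  (`>`), the homozygote-frequency and HWE filters inclusive (`>=`).
- MDS uses all post-QC SNPs by default; classical MDS cannot embed new
  individuals, so the transformer only supports fit_transform.
- Missing genotypes are mean-imputed to 2p per SNP for matrix analyses;
  the dominance coding interpolates linearly between class codes for
  imputed dosages.

## Known limitations

Dense O(n^3) REML limits the package to a few thousand individuals.
The GLS scan reuses one (s2_f, s2_e) estimate across SNPs; per-SNP
re-estimation would change results negligibly at ~40k SNPs but is not
implemented. Epistatic relationship matrices, Bayesian whole-genome
regression, haplotype association, permutation thresholds and
pedigree-only REML are out of scope.
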