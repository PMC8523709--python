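# Methods

This note documents the statistical model, the estimation choices, the
synthetic-data generator and the numerical conventions used by `funcprs`,
including the places where the design was genuinely open and what the package
chose.

## Model

Phenotypes are modeled as Y = Σᵢ βᵢ gᵢ + ε on the standardized scale, where
gᵢ are standardized genotypes and βᵢ normalized causal effects. Methods see
only marginal GWAS summary statistics. The normalized marginal effect of SNP
i is reconstructed from its p-value and sign,
β̃ᵢ = sign(b̂ᵢ)·Φ⁻¹(1 − pᵢ/2)/√N, which puts every cohort on the
correlation scale regardless of phenotype units. When a p-value underflows to
zero this quantile is infinite, so the per-allele estimate is rescaled
directly: β̃ᵢ = b̂ᵢ·√(2pᵢ(1−pᵢ))/√σ²_Y (pᵢ = minor allele frequency,
σ²_Y = training phenotypic variance).

### Posterior mean causal effects

Under an infinitesimal prior βᵢ ~ N(0, σ²) with σ² = h²_g/M, the posterior
mean given the local LD matrix **D** is the solution of

    (N·D + I/σ²) E[β | β̃, D] = N·β̃,

solved per LD window rather than by matrix inversion. The residual-LD factor
1/(1 − h²_l) multiplying N is approximated by 1, valid when each window
carries a small share of total heritability. Windows are contiguous,
non-overlapping, never span chromosomes, and hold round(M/3000) SNPs
(remainder in the final window, floored at one SNP).

The functionally informed variant replaces σ² with per-SNP variances: with
annotation values a_c(i) and coefficients τ_c,

    σ²ᵢ = Σ_c a_c(i)·τ_c ,

fitted values may be negative; those SNPs are removed (their effect is fixed
at zero) and a constant c = h²_g / Σ_{σ²ᵢ>0} σ²ᵢ rescales the remainder into
a proper prior. The solve becomes [N·D + (1/c)·diag(1/σ²ᵢ)]·E = N·β̃ over
the M₊ retained SNPs, with windows of round(0.0015·M₊) SNPs so window size
tracks the retained set.

τ_c is estimated by ordinary least squares of (χ²ᵢ − 1) on N·l(i,c), where
l(i,c) = Σⱼ r²ᵢⱼ a_c(j) is the per-annotation LD score within a radius
(default 1,000 kb). This is the moment condition of stratified LD-score
regression; the full S-LDSC machinery (regression weights, jackknifed
intercepts, reference-panel bias corrections) is intentionally out of scope.
A 1/max(l_base, 1) heteroskedasticity weighting is available behind a flag.
r² is the plain squared sample correlation with no small-sample bias
adjustment, so LD scores should be computed on the largest panel available;
the upward bias of r̂² is roughly 1/n per pair and accumulates over
neighbors. h²_g is a required input (external mixed-model or LD-score
estimates are the intended source); Σᵢ max(σ²ᵢ, 0) is offered as a logged
fallback only.

### Bin regularization

The infinitesimal solution over-shrinks large causal effects and
under-shrinks noise when the architecture is sparse. Rather than fitting a
sparsity parameter, the posterior means are ranked by squared value and cut
into K bins, each bin the smallest prefix extension whose cumulative squared
mass reaches k·S/K (S = total squared mass). Per-bin weights α_k are
estimated by 10-fold cross-validation on the validation cohort: within each
fold, α is the least-squares coefficient vector (with intercept, allowed to
be negative) of the phenotype on the K per-bin scores over the other nine
folds; reported accuracy is the mean held-out R² across folds, and the
deployable α is refit on all validation samples. Empty bins produce constant
score columns and get α = 0. The bin count

    K = min(100, ⌈0.9·N·h²_g/100⌉)

keeps the per-fold estimation sample at least 100 times larger than K; for
small validation cohorts K = 1 and the method reduces exactly to its
uniform-weight parent.

### Baselines, meta-analysis, evaluation

P+T clumps greedily by ascending p-value (ties broken by chromosome and
position, so results are order-invariant), removing unprocessed SNPs within
250 kb (configurable; only the r² grid is canonical) whose squared
correlation with the kept SNP exceeds R²_LD, then thresholds on p < P_T; the
grid is R²_LD ∈ {0.1, 0.2, 0.5, 0.8} × 14 thresholds from 1 to 10⁻⁸, tuned
on validation R². The LASSO variant shrinks each retained |β̃ᵢ| by
λ(P_T) = Φ⁻¹(1 − P_T/2)·sd(β̃); sd(β̃) is computed once across all analysis
SNPs (its scope is ambiguous in the source formulation — a per-SNP standard
error is the other reading). The shrunk magnitude is implemented literally
as | |β̃ᵢ| − λ |, i.e. magnitudes below λ reflect rather than truncate; a
`soft=True` flag gives max(|β̃ᵢ| − λ, 0) instead. The high-prior SNP set is
the top 10% (or 5%) of raw σ²ᵢ before positivity masking.

Multi-cohort scores combine as Σ γᵢ·PRSᵢ with γ either Nᵢ/ΣNᵢ
(fixed-effect) or fit by least squares with intercept on validation data
(reported with adjusted R², since the fit is in-sample); for the
bin-regularized method, γ is fit on the cohorts' infinitesimal functional
scores first, the weighted posterior means are combined, and binning + CV run
on the combination.

Accuracy is the squared Pearson correlation between score and phenotype;
calibration is the slope of phenotype on score (1 = calibrated). Standard
errors come from a 200-block genomic jackknife: contiguous variant blocks of
near-equal size (chromosome boundaries may fall inside a block), the
statistic recomputed with each block's SNPs removed from scoring while all
tuning parameters stay at their genome-wide values, and
SE² = (B−1)/B·Σ(θ₍b₎ − θ̄)². Method differences use paired delete-one
statistics.

## Synthetic data generator

The generator emulates the study design the methods target: two haplotypes
per individual are drawn independently; within an LD block, latent Gaussians
follow an AR(1) process with correlation `ld_rho` (default 0.6) and each
SNP's allele indicator thresholds the latent value at its MAF quantile
(MAF ~ U(0.05, 0.5)). Block sizes are geometric with mean 20 SNPs; SNPs sit
1 kb apart. This yields Hardy–Weinberg genotypes with tunable, distance-
decaying LD. Annotations are a base column of ones, Bernoulli(0.1) binary
indicators, and one continuous LD-score column (computed on up to 500
samples — adequate for an annotation value). The generative prior gives
binary-annotation carriers three times the base per-SNP variance and adds a
standardized continuous contribution, which drives a few percent of SNPs to
σ²ᵢ ≤ 0 and so exercises the masking path. Causal SNPs are a uniform random
fraction `p_causal`; causal effects are βᵢ ~ N(0, c·σ²ᵢ/p_causal), so the
expected summed squared effect equals h²_g, converted to per-allele scale by
bᵢ = βᵢ/√(2pᵢ(1−pᵢ)). Phenotypes are Y = Σ bᵢgᵢ + ε with
ε ~ N(0, 1 − h²_g); an `exact_h2` flag residualizes and rescales the noise
so the realized variance ratio is exact, for tight tests. Marginal GWAS is
per-SNP simple regression on the standardized genotype with
normal-approximation p-values — chosen over t-based p-values so that
reconstructing β̃ from p-values round-trips the z-score exactly; at the
sample sizes involved the difference is negligible.

What the generator does **not** emulate: realistic MAF spectra and LD decay
of real populations, relatedness and population structure, binary-trait
liability, imputation error, or annotation architectures beyond
binary + LD-related. Passing tests therefore demonstrate correctness of the
estimators under the stated generative model, and the expected qualitative
ordering of methods under sparse architectures — not real-data accuracy
levels.

## Numerical conventions and edge cases

- Genotype standardization uses the panel's own empirical mean and sample
  variance (ddof = 1); 2p(1−p) standardization is not used. Monomorphic
  variants raise an error naming the variant. Missing calls are mean-imputed
  per variant; all-missing variants are dropped with a warning.
- Validation-panel statistics standardize the scoring genotypes (the
  training-frequency alternative is defensible; validation standardization
  keeps scoring self-contained).
- Harmonization matches on (chromosome, position), reconciles allele order
  by flipping effect signs, drops A/T and C/G pairs when requested, drops
  both copies of duplicated positions, and applies MAF ≥ 0.01 and, when an
  INFO column is present, INFO ≥ 0.9 filters. It is idempotent.
- Positions are 1-based (BIM convention); exclusion regions are half-open
  [start, end), a variant exactly at `start` is masked.
- Window solves use `scipy.linalg.solve` with the symmetric-positive flag;
  the system matrix is positive definite whenever prior variances are
  positive, which the prior normalization guarantees.
- Bin boundaries use a 10⁻¹² relative tolerance when testing cumulative mass
  against k·S/K to absorb floating-point roundoff; the final bin always
  takes all remaining SNPs.
- p-value ties in clumping and σ²ᵢ ties in high-prior selection are broken
  by variant order (chromosome, position) for determinism.
- Every stochastic step (fold assignment, generator, causal sampling) takes
  an explicit seed; pipeline runs with identical configs and seeds produce
  byte-identical numeric outputs.

## Problem sizes in the shipped checks

The test suite and the reproduction script run entirely on synthetic data at
desk scale, chosen so the full suite completes in minutes on one CPU: the
replicate suites use M = 1,500–5,000 SNPs, training cohorts of 5,000–10,000
and validation cohorts of 1,500–2,000, with 20 seeded replicates per
quantity. These sizes are large enough that the Monte-Carlo standard errors
of the checked quantities (realized heritability, calibration slope, paired
R² differences) are an order of magnitude smaller than the effects being
verified.

## Known limitations

- The τ regression is unweighted OLS by default; with strong
  heteroskedasticity in χ² the coefficient standard errors (not computed
  here) would be optimistic, and the point estimates noisier than S-LDSC's.
- LD matrices are plain sample correlations per window; no shrinkage or
  banding, so very small reference panels produce noisy posterior means.
- Binary traits are handled as 0/1 quantitative phenotypes; no
  liability-scale conversion of R².
- The meta-analysis assumes cohort scores are computed on the same
  validation samples and variant set; cross-ancestry weighting is untested.
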