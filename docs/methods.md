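# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `penrisk`.  It is the design record of the package; every
empirical statement here is one the test suite or `scripts/acceptance.py`
actually computes.

## Synthetic cohorts

The generator (`penrisk.simulate`) produces the data a case-control
polygenic analysis assumes, under a liability-threshold model.

**Genotypes.** Each SNP is biallelic with a MAF drawn from a configurable
law (default uniform on [0.05, 0.5]) and genotypes in exact
Hardy-Weinberg proportions.  Linkage disequilibrium is modeled by latent
multivariate Gaussians: within a block of size m and parameter ρ, the
latent normals share a single common factor (`z_j = √ρ·f + √(1−ρ)·ε_j`),
and each latent value is cut at the HWE genotype quantiles of its SNP's
MAF.  This keeps marginals exactly HWE while giving tunable, positive
dosage correlation; it does not produce realistic recombination-map decay,
only block structure.  Missingness is injected completely at random —
cohort missingness is typically informative, which the QC tests therefore
do not probe.

**Phenotypes.** Liability = genetic score + covariate effects + Gaussian
noise.  The genetic score is a weighted sum of standardized causal
dosages with i.i.d. Gaussian weights, rescaled *exactly* so its sample
variance equals the requested h²; covariates contribute their squared
effect sizes; the residual absorbs the remainder so total liability
variance is 1 in expectation.  Cases are liabilities above the standard
normal (1−K) quantile for prevalence K.  A synthetic "age" column is
provided as the extreme-control selection covariate; by default it is
independent of liability (its correlation is an explicit knob,
`liability_age_corr`), because whether age tracks liability in a real
cohort is cohort-specific.

Consequences for interpretation: passing tests demonstrate correct
behavior under HWE, MCAR missingness, block LD and an additive liability
model.  They say nothing about non-additive effects, population
stratification beyond the two-subpopulation PCA check, genotyping batch
artifacts, or informative missingness.

## Quality control (`penrisk.io_qc`)

Filters use the standard GWAS thresholds, strict inequalities exactly as
stated: remove SNPs with exact-test HWE p < 1e-6, call rate < 95% or
MAF < 1%; remove samples with call rate < 95%, heterozygosity > 30%, or
pairwise mean IBS > 0.8.  Statistics are computed on nonmissing calls;
removal reasons are reported in the order (hwe, call_rate, maf).  The HWE
test is the exact conditional (Levene–Haldane) test, not mid-p and not
chi-square: it sums the probabilities of all heterozygote counts no more
probable than the observed one, conditional on allele counts.  For a
related pair the member with the lower call rate is dropped (tie: the
later sample in row order) — which member a real pipeline drops is
arbitrary, so the rule is simply fixed and documented.  Missing genotypes
are filled with the per-SNP mean dosage; downstream methods accept
fractional dosages, so no haplotype-based imputation is attempted.
Population structure is summarized by plain PCA of the column-standardized
dosage matrix (no outlier-removal iterations, no LD pruning); component
signs are fixed by making each score column's largest-magnitude entry
positive, which makes scores invariant to SNP order.

A note on small panels: with n samples the exact HWE test's smallest
attainable p-value is bounded below (at n = 20 it is 1.3e-6), so a
demonstration panel for the p < 1e-6 rule needs at least 24 samples —
hence the 20-SNP × 24-sample planted fixture in `penrisk.qc_fixture`.

## Screening and GRS (`penrisk.screening`)

The marker statistic is the between- to within-group sum-of-squares ratio
of dosages, with no degrees-of-freedom factor; multiplying by (n−2) gives
the classical one-way ANOVA F with (1, n−2) df, which is how p-values are
obtained (`p = Pr(F₁,ₙ₋₂ ≥ (n−2)F)`).  Top-p1 selection sorts F
descending with ties broken by ascending SNP index, and is only ever run
on training folds.  The GRS sums the dosages of SNPs significant at
α = 0.05; by default each SNP is oriented by the sign of its case-control
mean difference so protective and risk alleles do not cancel (an
unoriented raw sum is available via `orient=False`).  The score plus
environmental covariates are calibrated by an unpenalized logistic
regression fitted with Newton/IRLS and step halving; perfect separation
is detected (likelihood → 0 or diverging coefficients) and raised as an
error recommending a penalized model.

## Penalized solvers (`penrisk.penalized`)

The objective is the per-sample logistic negative log-likelihood plus
Σ J_λ(|β_j|) over penalized coordinates.  Choices that matter:

- **Standardization.** Predictors are standardized to unit variance
  internally and coefficients returned on the original scale, so one λ is
  comparable across SNPs of different MAF.  The recorded objective value
  refers to the standardized problem — the one the penalty acts on.
- **Intercept** is never penalized.  Environmental covariates are
  penalized by default (the penalty sum runs over all coefficients), with
  `penalize_covariates=False` to exempt them.
- **Elastic net** is λ(a·t + (1−a)·t²) — no ½ on the quadratic term.  To
  map to the glmnet parameterization λg(α·t + (1−α)/2·t²): α = a and
  λg(1−α)/2 = λ(1−a).
- **Grids.** 100 log-spaced λ values by default.  For lasso/SCAD the grid
  runs from λ_max (the smallest λ with an all-zero penalized fit, computed
  from the score of the null model) down to 0.01·λ_max; elastic net at
  mixing a > 0 rescales by 1/a; ridge and truncated ridge extend λ_max
  upward by one decade since a quadratic penalty has no finite λ_max.
  Elastic-net mixing defaults to 20 equally spaced values in [0, 1]; SCAD
  concavity defaults to a = 50 (exposed as a parameter — small a is known
  to be unstable and no principled selector exists); truncated-ridge
  levels default to 20 log-spaced values in [0.001, 0.01].
- **Algorithms.** Ridge: direct IRLS/Newton solves.  Lasso/elastic net:
  IRLS around a cyclic coordinate-descent inner solver (numba-compiled),
  warm-started along descending λ.  SCAD: local linear approximation — a
  sequence of weighted lasso problems with weights J′(|β|), initialized
  from the lasso solution at the same λ, at most 20 outer iterations.
  Truncated ridge: the ridge path with original-scale coefficients below
  the truncation level set to exactly zero (the intercept is never
  truncated).
- **Tolerances.** Coordinate-descent/IRLS coefficient-change tolerance
  1e-7 by default (tests that verify KKT conditions to 1e-6 tighten it),
  10,000 CD sweeps and 200 IRLS iterations maximum.
- **Separation.** At small λ on separable training data the unpenalized
  directions have no finite optimum.  The solver detects saturation
  (all fitted probabilities within 1e-3 of their labels) or coefficient
  drift beyond 100 on the standardized scale, stops, and flags the path
  entry as unconverged rather than failing; tuning then simply avoids
  such entries because their validation AUC is poor.
- **Tuning.** Stratified inner k-fold CV (default k = 5) on training data
  only, over the full (λ, a) grid, selecting either the highest mean
  validation AUC or the one-standard-error rule (sparsest grid point
  within one SE of the best).  Fold construction retries with a new seed
  if a fold lacks a class, then errors after 3 attempts.

## Mixed models (`penrisk.mixed_model`)

The genomic relationship matrix is A = ZZᵗ/m with Z the dosage matrix
standardized by allele frequency (centered at 2p̂, scaled by √(2p̂(1−p̂))).
The binary trait is analyzed on the observed 0/1 scale — matching common
GREML practice for case-control h² reporting when no ascertainment
correction is applied; no liability-scale transformation is provided, so
estimates from ascertained case-control samples are observed-scale
quantities only.  REML uses EM steps (monotone, used for the first
iterations and as a fallback) with average-information acceleration,
convergence at relative restricted-log-likelihood change < 1e-6, at most
200 iterations, and variances floored at 1e-6 × phenotypic variance — a
null trait therefore reports h² at or near 1e-6, with small positive
estimates possible from sampling noise.  Standard errors come from the
inverse AI matrix; the h² SE by the delta method.  With an identity
kernel only the total variance is identified: the fit stays stable and
conserves variance, but the genetic/residual split is arbitrary — this
degeneracy is tested as such.  MultiBLUP here means "multiple random
effects from a fixed SNP partition" (default: 2 MAF-quantile bins;
position windows available); the adaptive region-search of the full
published algorithm is out of scope.  BLUP prediction for test
individuals uses the train-test cross-blocks of kernels computed once
over all samples — those blocks involve no test phenotypes, so
cross-validation stays leakage-free.

## Experiment engine (`penrisk.evaluation`)

For each (n, p1) cell: subsample n individuals preserving the cohort
case:control ratio (extreme-control rule on the selection covariate when
available, otherwise random); split into k = 10 stratified folds (each
class dealt round-robin after a seeded shuffle); per fold, screen the top
p1 markers by F-ratio on the training split, fit every configured method
with tuning confined to the training split, and score the held-out fold
once.  AUC is the Mann-Whitney concordance probability (ties ½, via
scikit-learn).  The "replicates" of the design are the k test folds of
one partition; an outer replicate loop with fresh seeds is also provided.
Per-cell seeds derive from the master seed through a `SeedSequence`
counter scheme, so any single cell is independently reproducible.  Failed
cells are recorded with their error and excluded from aggregation with an
explicit count, never silently dropped.

## Problem sizes in tests and the acceptance script

The heavy checks run at deliberately moderate scale, chosen to make the
statistical assertions decisive while keeping the whole suite a
few-minute run on one CPU: solver-oracle comparisons at n ≤ 50, p ≤ 5
(25 instances per family); REML recovery at n = 500, m = 1000 over 50
replicates (mean within 3 Monte-Carlo SEs of the true 0.5); the null
cross-validation check at n = 400 over 10 folds × 3 replicates (mean AUC
in [0.45, 0.55] for all seven methods); and the infinitesimal-model
comparison (400 causal SNPs of 800, h² = 0.5, p1 = 200) at n = 200 and
n = 1600.  The qualitative orderings asserted there — ridge/truncated
ridge ≥ lasso/SCAD at small n, SCAD sparsest among the sparse families,
truncated-ridge complexity ≤ ridge everywhere, lasso improving with n —
are stochastic properties of that architecture, not theorems; they are
checked over ≥ 10 fold-replicates per cell.

## Known limitations

- Mean-dosage imputation ignores haplotype information.
- The 30% heterozygosity rule presumes a genotyping array's skewed MAF
  spectrum; a synthetic panel of uniformly common SNPs (MAF uniform on
  [0.05, 0.5]) has expected heterozygosity ≈ 0.37 and would be removed
  wholesale, so the threshold should be raised when applying sample QC to
  such panels (it is a parameter everywhere it appears).
- No liability-scale or ascertainment-corrected heritability.
- The LD model is block-constant correlation, not a recombination map.
- SCAD solutions are local optima (LLA from the lasso start); the
  orthonormal-design unbiasedness property is verified, global optimality
  cannot be.
- The experiment engine is single-process; genome-wide-scale performance
  engineering is out of scope.
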