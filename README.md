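# penrisk

Penalized and nonpenalized disease risk prediction from SNP genotypes.

`penrisk` is a Python library for building and comparing polygenic
disease-prediction models on case-control GWAS data.  It implements the
complete workflow a genetic-epidemiology analyst needs to benchmark
prediction methods: genotype/sample quality control, marginal marker
screening, genetic risk scores, mixed-model (GBLUP/MultiBLUP) prediction
with REML heritability estimation, five penalized logistic-regression
families, and a leakage-free cross-validated AUC experiment engine.
Because real cohort genotypes are usually access-controlled, the package
ships a first-class synthetic-data generator that reproduces the
statistical structure such an analysis assumes, so every stage is testable
end to end without any download.

## The model

For a dichotomous phenotype `y_i ∈ {0,1}` with covariate vector `x_i`
(p1 screened SNP dosages plus p2 environmental covariates), coefficients
are estimated by minimizing the penalized negative log-likelihood

    (1/n) Σ_i [ −y_i x_iᵗβ + log(1 + exp(x_iᵗβ)) ] + Σ_j J_λ(|β_j|)

with penalty families

| family          | J_λ(t)                                  | behaviour |
|-----------------|------------------------------------------|-----------|
| ridge           | λ t²                                     | dense shrinkage |
| lasso           | λ t                                      | shrinkage + selection |
| elastic net     | λ (a·t + (1−a)·t²)                       | between the two |
| SCAD            | J′ = min(λ, (aλ−t)₊/(a−1)), a > 2        | unbiased selection |
| truncated ridge | ridge, then zero all \|β_j\| < a          | sparse ridge |

Convex families are solved by IRLS with cyclic coordinate descent and warm
starts along a descending 100-point λ grid; SCAD by local linear
approximation from the lasso solution.  The nonpenalized comparators are a
genetic risk score (sum of dosages of SNPs marginally significant by the
F-ratio screen, calibrated by logistic regression) and MultiBLUP (a linear
mixed model with one random effect per SNP class, e.g. MAF bins, fitted by
AI-accelerated EM-REML).  Markers are pre-ranked by the F-ratio

    F_k = Σ_l n_l (x̄_kl − x̄_k)² / Σ_i (x_ik − x̄_{k,y_i})²

computed on training folds only, and models are compared by held-out AUC
across a grid of sample sizes n and marker counts p1.

## A worked example

```python
from penrisk import (ExperimentConfig, SimulationSpec, run_experiment,
                     simulate_study)

study = simulate_study(SimulationSpec(
    n_individuals=1000, n_snps=400, n_causal=200, h2=0.5,
    prevalence=0.35, seed=42))

config = ExperimentConfig(
    methods=["grs", "multiblup", "ridge", "lasso", "enet", "scad", "tr"],
    n_grid=[300, 700], p1_grid=[100], k_folds=5, inner_k=3, n_lambda=10,
    enet_mixing=[0.25, 0.5, 0.75], tr_levels=[0.001, 0.003, 0.01], seed=1)

print(run_experiment(study, config).aggregate().to_string(index=False))
```

prints (excerpt)

```
   method   n  p1  mean_auc  sd_auc  mean_nonzero  cells  failed_cells
      grs 300 100     0.530   0.055        25.200      5         0.000
    ridge 300 100     0.620   0.091       100.000      5         0.000
    lasso 300 100     0.585   0.096        81.800      5         0.000
    ridge 700 100     0.645   0.061       100.000      5         0.000
    lasso 700 100     0.640   0.061        97.600      5         0.000
```

Each row is the mean held-out AUC and mean retained-SNP count for one
method at one sample size: under this many-small-effects simulation the
dense ridge leads at n = 300, while the lasso closes the gap at n = 700
using fewer SNPs — the characteristic dense-versus-sparse trade-off this
package is built to expose.

The `examples/` directory holds one short script per capability
(simulation, QC, screening/GRS, penalized paths, heritability, the CV
experiment); each prints its results with a line of interpretation.  A thin
CLI mirrors the library (`penrisk simulate | qc | screen | grs | fit | h2 |
cv-experiment`); run `penrisk --help`.

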