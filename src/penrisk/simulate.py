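"""Synthetic case-control GWAS data under a liability-threshold model.

The generator produces biallelic SNPs in Hardy-Weinberg equilibrium at MAFs
drawn from a configurable law, optional LD blocks realized by thresholding
block-correlated latent Gaussians at the HWE genotype quantiles, and a binary
phenotype obtained by thresholding a latent liability at the quantile implied
by the disease prevalence.  The genetic contribution to liability is rescaled
exactly so that its empirical variance share equals the requested
narrow-sense heritability h2; environmental covariates add fixed effects and
the residual absorbs the remainder so the liability has unit variance in
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .types import GenotypeMatrix, PhenotypeTable


@dataclass
class SimulationSpec:
    """Study-design parameters for one synthetic dataset.

    Parameters
    ----------
    n_individuals, n_snps
        Cohort and marker-panel sizes.
    maf_law
        Either a (low, high) tuple for a uniform MAF law on (0, 0.5], or an
        explicit per-SNP MAF array of length ``n_snps``.
    ld_blocks
        List of (block_size, rho) pairs; consecutive SNPs are grouped into
        blocks whose latent Gaussians share correlation rho in [0, 1).
        SNPs not covered by any block are independent.
    n_causal
        Number of causal SNPs (chosen uniformly at random without
        replacement).
    h2
        Liability-scale narrow-sense heritability in [0, 1].
    prevalence
        Disease prevalence K in (0, 1); cases are liabilities above the
        standard-normal (1-K) quantile.
    env_covariates
        List of (name, effect) pairs; each covariate is standard normal and
        enters the liability with the stated coefficient.
    missing_rate
        Probability that any single genotype call is missing (completely at
        random).
    liability_age_corr
        Correlation between the synthetic "age" selection covariate and the
        liability; defaults to 0 (independence).
    """

    n_individuals: int
    n_snps: int
    maf_law: tuple[float, float] | np.ndarray = (0.05, 0.5)
    ld_blocks: list[tuple[int, float]] = field(default_factory=list)
    n_causal: int = 0
    h2: float = 0.0
    prevalence: float = 0.5
    env_covariates: list[tuple[str, float]] = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0
    liability_age_corr: float = 0.0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not (0 <= self.n_causal <= self.n_snps):
            raise ValueError("n_causal must lie in [0, n_snps]")
        if not (isinstance(self.h2, (int, float)) and 0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must lie in [0, 1]")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if sum(b for b, _ in self.ld_blocks) > self.n_snps:
            raise ValueError("ld_blocks sizes sum beyond n_snps")
        for size, rho in self.ld_blocks:
            if size < 1 or not (0.0 <= rho < 1.0):
                raise ValueError("ld_blocks entries must be (size>=1, rho in [0,1))")
        if isinstance(self.maf_law, tuple):
            lo, hi = self.maf_law
            if not (0.0 < lo <= hi <= 0.5):
                raise ValueError("maf_law range must satisfy 0 < low <= high <= 0.5")
        else:
            m = np.asarray(self.maf_law, dtype=float)
            if m.shape != (self.n_snps,) or not ((m > 0) & (m <= 0.5)).all():
                raise ValueError("maf_law array must give per-SNP MAFs in (0, 0.5]")
        cov_var = sum(c**2 for _, c in self.env_covariates)
        if self.h2 + cov_var > 1.0 + 1e-12:
            raise ValueError("h2 plus covariate variance exceeds liability variance 1")


@dataclass
class StudySample:
    """A simulated cohort plus the generating truth."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    causal_indices: np.ndarray
    causal_effects: np.ndarray
    liabilities: np.ndarray


def _draw_mafs(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec.maf_law, tuple):
        lo, hi = spec.maf_law
        return rng.uniform(lo, hi, size=spec.n_snps)
    return np.asarray(spec.maf_law, dtype=float).copy()


def simulate_genotypes(spec: SimulationSpec, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw an n x p dosage matrix in HWE with optional LD blocks.

    Within an LD block the latent Gaussians of the member SNPs share a
    constant correlation rho; dosages arise by cutting each latent normal at
    the HWE genotype quantiles of that SNP's MAF, so marginal genotype
    frequencies are exactly HWE while adjacent dosages correlate.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n, p = spec.n_individuals, spec.n_snps
    mafs = _draw_mafs(spec, rng)

    z = rng.standard_normal((n, p))
    # overlay block structure: z_j = sqrt(rho) f_block + sqrt(1-rho) eps_j
    start = 0
    for size, rho in spec.ld_blocks:
        if rho > 0:
            shared = rng.standard_normal((n, 1))
            z[:, start : start + size] = (
                np.sqrt(rho) * shared + np.sqrt(1 - rho) * z[:, start : start + size]
            )
        start += size

    u = norm.cdf(z)
    q = mafs  # minor allele frequency
    # HWE genotype probs for dosage counting the minor allele:
    # P(0)=(1-q)^2, P(1)=2q(1-q), P(2)=q^2
    thr0 = (1 - q) ** 2
    thr1 = thr0 + 2 * q * (1 - q)
    dos = np.where(u < thr0, 0.0, np.where(u < thr1, 1.0, 2.0))

    if spec.missing_rate > 0:
        mask = rng.random((n, p)) < spec.missing_rate
        dos[mask] = np.nan

    meta = pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(p)],
            "chrom": 1,
            "pos": np.arange(1, p + 1) * 1000,
            "allele1": "A",
            "allele2": "G",
            "maf": mafs,
        }
    )
    ids = [f"ind{i}" for i in range(n)]
    return GenotypeMatrix(ids, meta, dos)


def simulate_phenotype(
    G: GenotypeMatrix,
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
) -> tuple[PhenotypeTable, StudySample]:
    """Liability-threshold binary phenotype on top of simulated genotypes.

    liability = genetic score + covariate effects + Gaussian noise, with the
    genetic score rescaled so its sample variance is exactly h2 and the noise
    variance chosen so the total liability variance is 1 in expectation.
    Cases are liabilities above the standard-normal (1 - prevalence)
    quantile.  Missing dosages are mean-imputed on the fly for the score.
    """
    spec.validate()
    if not np.isfinite(spec.h2):
        raise ValueError("h2 must be finite")
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    n = G.n_samples

    dos = G.dosages
    if np.isnan(dos).any():
        col_mean = np.nanmean(dos, axis=0)
        dos = np.where(np.isnan(dos), col_mean[None, :], dos)

    causal = np.sort(rng.choice(G.n_snps, size=spec.n_causal, replace=False))
    effects = rng.standard_normal(spec.n_causal)
    g = np.zeros(n)
    if spec.n_causal > 0 and spec.h2 > 0:
        Z = dos[:, causal]
        sd = Z.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (Z - Z.mean(axis=0)) / sd
        g = Z @ effects
        gv = g.var()
        if gv > 0:
            scale = np.sqrt(spec.h2 / gv)
            g *= scale
            effects = effects * scale
        else:
            g = np.zeros(n)
            effects = np.zeros(spec.n_causal)
    else:
        effects = np.zeros(spec.n_causal)

    cov_cols = {}
    cov_part = np.zeros(n)
    for name, eff in spec.env_covariates:
        x = rng.standard_normal(n)
        cov_cols[name] = x
        cov_part += eff * x

    cov_var = sum(c**2 for _, c in spec.env_covariates)
    resid_var = max(1.0 - spec.h2 - cov_var, 0.0)
    noise = np.sqrt(resid_var) * rng.standard_normal(n)
    liability = g + cov_part + noise

    threshold = norm.ppf(1.0 - spec.prevalence)
    y = (liability > threshold).astype(int)

    # synthetic "age": the extreme-control selection covariate; optionally
    # correlated with liability
    r = float(spec.liability_age_corr)
    age = r * liability + np.sqrt(max(1 - r**2, 0.0)) * rng.standard_normal(n)

    table = pd.DataFrame({"sample_id": G.sample_ids, "y": y, "liability": liability, "age": age})
    for name, x in cov_cols.items():
        table[name] = x
    pheno = PhenotypeTable(table, covariates=[name for name, _ in spec.env_covariates])
    truth = StudySample(G, pheno, causal, effects, liability)
    return pheno, truth


def simulate_study(spec: SimulationSpec) -> StudySample:
    """Genotypes and phenotype from one seed; the usual entry point."""
    rng = np.random.default_rng(spec.seed)
    G = simulate_genotypes(spec, rng)
    _, truth = simulate_phenotype(G, spec, rng)
    return truth


def select_case_control(
    pheno: PhenotypeTable,
    n_a: int,
    n_u: int,
    control_rule: str = "random",
    selection_covariate: str = "age",
    seed: int = 0,
) -> np.ndarray:
    """Pick n_a cases and n_u controls from the pool.

    Under the ``extreme`` rule the selected controls are the unaffected
    individuals with the highest values of ``selection_covariate`` (the
    synthetic analogue of choosing the oldest unaffected individuals);
    ``random`` samples controls uniformly.  Cases are sampled uniformly
    either way.  Returns positional indices, cases first.
    """
    if control_rule not in ("random", "extreme"):
        raise ValueError(f"unknown control_rule {control_rule!r}")
    y = pheno.y
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    if len(cases) < n_a or len(controls) < n_u:
        raise ValueError(
            f"insufficient pool: need {n_a} cases / {n_u} controls, "
            f"have {len(cases)} / {len(controls)}"
        )
    rng = np.random.default_rng(seed)
    sel_cases = rng.choice(cases, size=n_a, replace=False)
    if control_rule == "random":
        sel_controls = rng.choice(controls, size=n_u, replace=False)
    else:
        if selection_covariate not in pheno.table.columns:
            raise ValueError(f"selection covariate {selection_covariate!r} absent")
        vals = pheno.table[selection_covariate].to_numpy(dtype=float)[controls]
        order = np.argsort(-vals, kind="stable")
        sel_controls = controls[order[:n_u]]
    return np.concatenate([np.sort(sel_cases), np.sort(sel_controls)])


# ---------------------------------------------------------------------------
# writers

def write_dosage_tsv(G: GenotypeMatrix, path: str) -> None:
    df = pd.DataFrame(G.dosages, columns=G.snp_ids)
    df.insert(0, "sample_id", G.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_ped_map(G: GenotypeMatrix, prefix: str) -> None:
    """PLINK text .ped/.map; missing calls become '0 0'.

    Fractional (imputed) dosages cannot be represented and raise.
    """
    dos = G.dosages
    ok = np.isnan(dos) | np.isin(dos, [0.0, 1.0, 2.0])
    if not ok.all():
        raise ValueError("ped format cannot represent fractional dosages")
    a1 = G.snp_meta["allele1"].to_numpy()
    a2 = G.snp_meta["allele2"].to_numpy()
    with open(f"{prefix}.map", "w") as fh:
        for _, row in G.snp_meta.iterrows():
            fh.write(f"{row['chrom']}\t{row['id']}\t0\t{row['pos']}\n")
    with open(f"{prefix}.ped", "w") as fh:
        for i, sid in enumerate(G.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j in range(G.n_snps):
                d = dos[i, j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [a2[j], a2[j]]
                elif d == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a1[j], a1[j]]
            fh.write(" ".join(fields) + "\n")


def write_raw(G: GenotypeMatrix, path: str) -> None:
    """PLINK .raw additive coding; the counted allele is the minor allele."""
    header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"] + [
        f"{sid}_{a1}" for sid, a1 in zip(G.snp_ids, G.snp_meta["allele1"])
    ]
    with open(path, "w") as fh:
        fh.write(" ".join(header) + "\n")
        for i, sid in enumerate(G.sample_ids):
            vals = [
                "NA" if np.isnan(d) else (f"{d:g}")
                for d in G.dosages[i]
            ]
            fh.write(" ".join([sid, sid, "0", "0", "0", "-9"] + vals) + "\n")


def write_truth(truth: StudySample, path: str) -> None:
    ids = [truth.genotypes.snp_ids[j] for j in truth.causal_indices]
    pd.DataFrame({"snp_id": ids, "effect": truth.causal_effects}).to_csv(
        path, sep="\t", index=False
    )
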