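"""Cross-validated AUC experiment engine.

Reproduces the study design of the method comparison: subsample n
individuals at a fixed case:control ratio, split them into stratified
folds, screen the top p1 markers by F-ratio on each training split only,
fit every configured method (GRS, MultiBLUP, ridge, lasso, elastic net,
SCAD, truncated ridge) with its tuning search confined to the training
split, and score the held-out fold.  The result is a tidy table of test
AUC and model complexity per (method, n, p1, fold, replicate) cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import penalized
from .mixed_model import kernels_from_partition, multiblup_predict, partition_snps, reml_fit
from .penalized import PenaltySpec, predict_prob, select_tuning
from .screening import grs_model, screen_top
from .simulate import StudySample, select_case_control
from .types import GenotypeMatrix, PhenotypeTable

METHODS = ("grs", "multiblup", "ridge", "lasso", "enet", "scad", "tr")

_FAMILY = {
    "ridge": "ridge",
    "lasso": "lasso",
    "enet": "elastic_net",
    "scad": "scad",
    "tr": "truncated_ridge",
}


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney concordance probability; ties count one half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def stratified_folds(y: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Fold labels 0..k-1 with cases and controls spread as evenly as possible.

    Each class is shuffled and dealt round-robin, so fold sizes within a
    class differ by at most one; remainders land on the lowest fold
    numbers.  Deterministic under the seed.
    """
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls} has {len(idx)} samples, fewer than k={k}")
        idx = rng.permutation(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


@dataclass
class ExperimentConfig:
    """Grid of methods, sample sizes and screened-marker counts to run."""

    methods: list[str] = field(default_factory=lambda: list(METHODS))
    n_grid: list[int] = field(default_factory=lambda: [200, 400, 800, 1600])
    p1_grid: list[int] = field(default_factory=lambda: [200])
    k_folds: int = 10
    n_replicates: int = 1
    tuning_rule: str = "max_auc"
    inner_k: int = 5
    n_lambda: int = 100
    enet_mixing: list[float] | None = None
    tr_levels: list[float] | None = None
    scad_a: float = 50.0
    control_rule: str = "extreme"
    seed: int = 0

    def validate(self, n_available: int | None = None) -> None:
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise ValueError(f"unknown methods {bad}; choose from {METHODS}")
        if not self.methods or not self.n_grid or not self.p1_grid:
            raise ValueError("methods, n_grid and p1_grid must be nonempty")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if n_available is not None and max(self.n_grid) > n_available:
            raise ValueError(
                f"n_grid maximum {max(self.n_grid)} exceeds the {n_available} available samples"
            )


@dataclass
class CVExperimentResult:
    """Tidy per-cell results plus aggregation helpers."""

    table: pd.DataFrame
    config: ExperimentConfig

    def aggregate(self) -> pd.DataFrame:
        ok = self.table[self.table["failed"] == False]  # noqa: E712
        agg = (
            ok.groupby(["method", "n", "p1"])
            .agg(
                mean_auc=("auc", "mean"),
                sd_auc=("auc", "std"),
                mean_nonzero=("nonzero", "mean"),
                cells=("auc", "size"),
            )
            .reset_index()
        )
        n_failed = (
            self.table[self.table["failed"]]
            .groupby(["method", "n", "p1"])
            .size()
            .rename("failed_cells")
            .reset_index()
        )
        return agg.merge(n_failed, on=["method", "n", "p1"], how="left").fillna(
            {"failed_cells": 0}
        )

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _cell_seed(master: int, rep: int, n: int, p1: int, fold: int = 0) -> int:
    """Deterministic per-cell seed below 2^31 via a seed-sequence hash."""
    return int(np.random.SeedSequence([master, rep, n, p1, fold]).generate_state(1)[0] % (2**31))


def _penalty_spec(method: str, cfg: ExperimentConfig) -> PenaltySpec:
    fam = _FAMILY[method]
    mixing = None
    if fam == "elastic_net" and cfg.enet_mixing is not None:
        mixing = np.asarray(cfg.enet_mixing, dtype=float)
    elif fam == "scad":
        mixing = np.array([cfg.scad_a])
    elif fam == "truncated_ridge" and cfg.tr_levels is not None:
        mixing = np.asarray(cfg.tr_levels, dtype=float)
    return PenaltySpec(family=fam, n_lambda=cfg.n_lambda, mixing_grid=mixing)


def _fit_and_score_method(
    method: str,
    cfg: ExperimentConfig,
    G_sub: GenotypeMatrix,
    X_snps: np.ndarray,
    cov: np.ndarray,
    y: np.ndarray,
    top: np.ndarray,
    tr_idx: np.ndarray,
    te_idx: np.ndarray,
    seed: int,
) -> tuple[float, int, float, float]:
    """Returns (auc, nonzero, lambda, a) for one method on one fold."""
    Xsel = X_snps[:, top]
    if method == "grs":
        m = grs_model(Xsel[tr_idx], y[tr_idx], cov[tr_idx] if cov.size else None)
        scores = m.predict_prob(Xsel[te_idx], cov[te_idx] if cov.size else None)
        return auc(scores, y[te_idx]), len(m.selected), np.nan, np.nan
    if method == "multiblup":
        ksub = G_sub.subset(snps=top)
        labels = partition_snps(ksub, "maf_bins:2")
        kernels = kernels_from_partition(ksub, labels, scheme="maf_bins:2")
        vc = reml_fit(y[tr_idx], cov[tr_idx] if cov.size else None,
                      _restrict_kernels(kernels, tr_idx))
        scores = multiblup_predict(
            vc, kernels, y[tr_idx], cov if cov.size else None, tr_idx, te_idx
        )
        return auc(scores, y[te_idx]), len(top), np.nan, np.nan

    design = np.column_stack([cov, Xsel]) if cov.size else Xsel
    n_cov = cov.shape[1] if cov.size else 0
    spec = _penalty_spec(method, cfg)
    sel = select_tuning(
        design[tr_idx], y[tr_idx], spec, n_covariates=n_cov,
        rule=cfg.tuning_rule, inner_k=cfg.inner_k, seed=seed,
    )
    scores = predict_prob(sel.model, design[te_idx])
    return (
        auc(scores, y[te_idx]),
        penalized.nonzero_snps(sel.model),
        sel.lam,
        sel.a if sel.a is not None else np.nan,
    )


def _restrict_kernels(kernels, idx):
    from .mixed_model import KernelSet

    return KernelSet(
        kernels=[A[np.ix_(idx, idx)] for A in kernels.kernels],
        group_labels=list(kernels.group_labels),
        scheme=kernels.scheme,
    )


def run_experiment(data: StudySample, config: ExperimentConfig) -> CVExperimentResult:
    """Run the full (method x n x p1 x fold x replicate) grid.

    Screening and tuning only ever see training rows; the held-out fold is
    touched once, to compute its AUC.  Failed cells are recorded with
    ``failed=True`` rather than dropped.
    """
    config.validate(n_available=data.genotypes.n_samples)
    G = data.genotypes
    pheno = data.phenotypes
    if np.isnan(G.dosages).any():
        raise ValueError("run QC / imputation before the experiment")
    y_all = pheno.y
    cov_all = pheno.covariate_matrix()
    n_cases = int(y_all.sum())
    n_controls = len(y_all) - n_cases
    rows = []
    for rep in range(config.n_replicates):
        for n in config.n_grid:
            n_a = int(round(n * n_cases / len(y_all)))
            n_a = min(max(n_a, 1), n - 1)
            n_u = n - n_a
            sel_seed = _cell_seed(config.seed, rep, n, 0)
            rule = config.control_rule
            if rule == "extreme" and "age" not in pheno.table.columns:
                rule = "random"
            idx = select_case_control(pheno, n_a, n_u, control_rule=rule, seed=sel_seed)
            G_sub = G.subset(samples=idx)
            y = y_all[idx]
            cov = cov_all[idx] if cov_all.size else np.empty((len(idx), 0))
            X_snps = G_sub.dosages
            folds = stratified_folds(y, k=config.k_folds, seed=sel_seed + 1)
            for p1 in config.p1_grid:
                for fold in range(config.k_folds):
                    te_idx = np.flatnonzero(folds == fold)
                    tr_idx = np.flatnonzero(folds != fold)
                    assert np.intersect1d(tr_idx, te_idx).size == 0  # leakage guard
                    top = screen_top(X_snps[tr_idx], y[tr_idx], p1)
                    cell_seed = _cell_seed(config.seed, rep, n, p1, fold)
                    for method in config.methods:
                        rec = {
                            "method": method,
                            "n": n,
                            "p1": p1,
                            "fold": fold,
                            "replicate": rep,
                            "auc": np.nan,
                            "nonzero": np.nan,
                            "lambda": np.nan,
                            "a": np.nan,
                            "failed": False,
                        }
                        try:
                            a_val, nz, lam, mix = _fit_and_score_method(
                                method, config, G_sub, X_snps, cov, y, top,
                                tr_idx, te_idx, cell_seed,
                            )
                            rec.update(auc=a_val, nonzero=nz, **{"lambda": lam}, a=mix)
                        except Exception as err:  # failed cell, run continues
                            rec["failed"] = True
                            rec["error"] = f"{type(err).__name__}: {err}"
                        rows.append(rec)
    table = pd.DataFrame(rows)
    if "error" not in table.columns:
        table["error"] = ""
    return CVExperimentResult(table, config)


def plot_auc(result: CVExperimentResult, path: str) -> None:
    """Mean test AUC against n, one panel per p1 (accuracy versus sample size)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = result.aggregate()
    p1s = sorted(agg["p1"].unique())
    fig, axes = plt.subplots(1, len(p1s), figsize=(4 * len(p1s), 3.2), squeeze=False)
    for ax, p1 in zip(axes[0], p1s):
        sub = agg[agg["p1"] == p1]
        for method in sorted(sub["method"].unique()):
            s = sub[sub["method"] == method].sort_values("n")
            ax.plot(s["n"], s["mean_auc"], marker="o", label=method)
        ax.set_title(f"p1 = {p1}")
        ax.set_xlabel("n")
        ax.set_ylabel("test AUC")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_nonzero(result: CVExperimentResult, path: str) -> None:
    """Mean nonzero-SNP count against n (model complexity versus sample size)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = result.aggregate()
    p1s = sorted(agg["p1"].unique())
    fig, axes = plt.subplots(1, len(p1s), figsize=(4 * len(p1s), 3.2), squeeze=False)
    for ax, p1 in zip(axes[0], p1s):
        sub = agg[agg["p1"] == p1]
        for method in sorted(sub["method"].unique()):
            s = sub[sub["method"] == method].sort_values("n")
            ax.plot(s["n"], s["mean_nonzero"], marker="o", label=method)
        ax.set_title(f"p1 = {p1}")
        ax.set_xlabel("n")
        ax.set_ylabel("nonzero SNPs")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
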