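"""Marginal F-ratio screening and the genetic-risk-score model.

The screening statistic for marker k is the ratio of the between-group to
the within-group sum of squares of its dosages across cases and controls,

    F_k = sum_l n_l (xbar_kl - xbar_k)^2  /  sum_i (x_ik - xbar_{k,y_i})^2 ,

without degrees-of-freedom scaling; (n - 2) * F_k is the classical one-way
ANOVA F statistic with (1, n - 2) df, which provides the p-value mapping
used for the significance cut in the GRS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist


def f_ratio(x: np.ndarray, y: np.ndarray) -> float:
    """Between- to within-group sum-of-squares ratio of one dosage vector.

    Returns ``inf`` when the within-group variation is zero but the group
    means differ; raises if only one class is present.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y lengths differ")
    m0, m1 = x[y == 0], x[y == 1]
    if len(m0) == 0 or len(m1) == 0:
        raise ValueError("both classes must be present")
    xbar = x.mean()
    num = len(m0) * (m0.mean() - xbar) ** 2 + len(m1) * (m1.mean() - xbar) ** 2
    den = ((m0 - m0.mean()) ** 2).sum() + ((m1 - m1.mean()) ** 2).sum()
    if den == 0:
        return 0.0 if num == 0 else np.inf
    return float(num / den)


def f_ratio_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized :func:`f_ratio` over the columns of X."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    mask1 = y == 1
    n1, n0 = int(mask1.sum()), int((~mask1).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    mean1 = X[mask1].mean(axis=0)
    mean0 = X[~mask1].mean(axis=0)
    grand = X.mean(axis=0)
    num = n1 * (mean1 - grand) ** 2 + n0 * (mean0 - grand) ** 2
    den = ((X[mask1] - mean1) ** 2).sum(axis=0) + ((X[~mask1] - mean0) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = num / den
    F = np.where(den == 0, np.where(num == 0, 0.0, np.inf), F)
    return F


def f_ratio_pvalues(F: np.ndarray, n: int) -> np.ndarray:
    """Map raw F-ratios to p-values via (n-2)*F ~ F(1, n-2) under the null."""
    F = np.asarray(F, dtype=float)
    out = np.where(np.isinf(F), 0.0, f_dist.sf((n - 2) * np.where(np.isinf(F), 0, F), 1, n - 2))
    return out


@dataclass
class FRatioResult:
    """Per-SNP screening statistics."""

    f_values: np.ndarray
    ranks: np.ndarray  # rank[j] = position of SNP j in the descending-F order
    p_values: np.ndarray

    def to_frame(self, snp_ids: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": snp_ids, "F": self.f_values, "rank": self.ranks, "p": self.p_values}
        )


def f_ratio_result(X: np.ndarray, y: np.ndarray) -> FRatioResult:
    F = f_ratio_matrix(X, y)
    order = np.lexsort((np.arange(len(F)), -F))  # descending F, ties -> lower index
    ranks = np.empty(len(F), dtype=int)
    ranks[order] = np.arange(len(F))
    return FRatioResult(F, ranks, f_ratio_pvalues(F, len(y)))


def screen_top(X: np.ndarray, y: np.ndarray, p1: int) -> np.ndarray:
    """Indices of the p1 largest F-ratio columns, descending, ties by index.

    Must be called on training data only; asking for more SNPs than exist
    returns all of them with a warning.
    """
    if p1 < 1:
        raise ValueError("p1 must be >= 1")
    F = f_ratio_matrix(X, y)
    order = np.lexsort((np.arange(len(F)), -F))
    if p1 >= len(F):
        if p1 > len(F):
            warnings.warn(
                f"p1={p1} exceeds the {len(F)} available SNPs; returning all",
                stacklevel=2,
            )
        return order
    return order[:p1]


# ---------------------------------------------------------------------------
# unpenalized logistic regression (IRLS with step halving)

class PerfectSeparationError(RuntimeError):
    pass


def logistic_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10) -> np.ndarray:
    """Maximum-likelihood logistic fit; X must not include an intercept column.

    Newton/IRLS with step halving on the log-likelihood.  Raises
    :class:`PerfectSeparationError` when the fit diverges (complete or
    quasi-complete separation), in which case a penalized fit is advisable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    D = np.column_stack([np.ones(n), X])
    beta = np.zeros(D.shape[1])

    def nll(b):
        eta = D @ b
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    cur = nll(beta)
    for _ in range(max_iter):
        eta = D @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1 - p), 1e-10, None)
        grad = D.T @ (y - p)
        H = (D * w[:, None]).T @ D
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as e:
            raise PerfectSeparationError(
                "singular Hessian in logistic fit; consider penalization"
            ) from e
        t = 1.0
        for _ in range(50):
            new = nll(beta + t * step)
            if new <= cur + 1e-14:
                break
            t /= 2.0
        beta = beta + t * step
        if np.max(np.abs(beta)) > 1e3 or new < 1e-4:
            # likelihood driven to zero / coefficients unbounded
            raise PerfectSeparationError(
                "perfect separation in logistic fit; use a penalized model"
            )
        if abs(cur - new) < tol * (abs(cur) + 1.0):
            cur = new
            break
        cur = new
    return beta


@dataclass
class GRSModel:
    """Genetic risk score model: signed dosage sum + logistic calibration.

    ``selected`` are column indices into the SNP matrix the model was built
    on; ``signs`` orient each selected SNP so its risk allele adds
    positively; ``beta`` holds (intercept, GRS, covariates) coefficients.
    ``covariate_only`` flags the degenerate no-significant-SNP case.
    """

    selected: np.ndarray
    signs: np.ndarray
    beta: np.ndarray
    alpha: float
    covariate_only: bool

    def grs(self, X_snps: np.ndarray) -> np.ndarray:
        if len(self.selected) == 0:
            return np.zeros(X_snps.shape[0])
        return X_snps[:, self.selected] @ self.signs

    def predict_prob(self, X_snps: np.ndarray, covariates: np.ndarray | None = None) -> np.ndarray:
        n = X_snps.shape[0]
        cov = np.empty((n, 0)) if covariates is None else np.asarray(covariates, dtype=float)
        D = np.column_stack([np.ones(n), self.grs(X_snps), cov])
        return 1.0 / (1.0 + np.exp(-(D @ self.beta)))


def grs_model(
    X_snps: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    alpha: float = 0.05,
    orient: bool = True,
) -> GRSModel:
    """Build a GRS on the training data.

    SNPs marginally significant at level ``alpha`` (F-ratio p-value) are
    summed into the score; with ``orient`` on, each SNP enters with the sign
    of its case-control mean dosage difference so protective and risk
    alleles do not cancel.  The score and environmental covariates are then
    calibrated by an unpenalized logistic regression.
    """
    X_snps = np.asarray(X_snps, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    cov = np.empty((n, 0)) if covariates is None else np.asarray(covariates, dtype=float)

    res = f_ratio_result(X_snps, y)
    selected = np.flatnonzero(res.p_values < alpha)
    if orient and len(selected):
        diff = X_snps[y == 1][:, selected].mean(axis=0) - X_snps[y == 0][:, selected].mean(axis=0)
        signs = np.where(diff >= 0, 1.0, -1.0)
    else:
        signs = np.ones(len(selected))

    covariate_only = len(selected) == 0
    if covariate_only:
        beta_cov = logistic_fit(cov, y)
        beta = np.concatenate([[beta_cov[0], 0.0], beta_cov[1:]])
    else:
        score = X_snps[:, selected] @ signs
        beta = logistic_fit(np.column_stack([score, cov]), y)
    return GRSModel(selected, signs, beta, alpha, covariate_only)
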