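"""Genomic relationship matrices, REML variance components, and (Multi)BLUP.

The binary phenotype is treated on the observed 0/1 scale with a linear
mixed model

    y = X b + sum_k g_k + e,   g_k ~ N(0, A_k s2_k),   e ~ N(0, I s2_e),

where each A_k is a genomic relationship matrix built from a class of SNPs
(one class gives GBLUP; several — e.g. MAF bins or position windows — give
the multi-kernel MultiBLUP form).  Variance components are estimated by
EM-REML with average-information (AI) acceleration; h2 = sum_k s2_k /
(sum_k s2_k + s2_e) with a delta-method standard error from the inverse AI
matrix.  No ascertainment correction is applied, so on case-control data
the estimate is the observed-scale quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import GenotypeMatrix


@dataclass
class KernelSet:
    """Named genomic relationship matrices over a common set of samples."""

    kernels: list[np.ndarray]
    group_labels: list[str] = field(default_factory=list)
    scheme: str = "single"

    def __post_init__(self) -> None:
        if not self.kernels:
            raise ValueError("at least one kernel required")
        n = self.kernels[0].shape[0]
        for A in self.kernels:
            if A.shape != (n, n):
                raise ValueError("kernels must be square and conformable")
            if not np.allclose(A, A.T, atol=1e-8):
                raise ValueError("kernels must be symmetric")
        if not self.group_labels:
            self.group_labels = [f"g{k}" for k in range(len(self.kernels))]

    @property
    def n(self) -> int:
        return self.kernels[0].shape[0]


@dataclass
class VarianceComponents:
    """REML estimates on the observed phenotype scale."""

    sigma2_g: np.ndarray          # one per kernel
    sigma2_e: float
    h2: float
    se_sigma2: np.ndarray         # per kernel + residual, same order
    se_h2: float
    loglik: float
    iterations: int
    converged: bool
    group_labels: list[str] = field(default_factory=list)


def grm(G: GenotypeMatrix, snp_subset: np.ndarray | None = None) -> np.ndarray:
    """VanRaden-style relationship matrix A = Z Z' / m over a SNP subset.

    Z standardizes each dosage column by its allele frequency: centered at
    2*p_hat and scaled by sqrt(2*p_hat*(1-p_hat)).  Monomorphic SNPs make
    the scale degenerate and must be removed by QC first.
    """
    dos = G.dosages
    if np.isnan(dos).any():
        raise ValueError("impute missing genotypes before computing a GRM")
    cols = np.arange(G.n_snps) if snp_subset is None else np.asarray(snp_subset)
    if len(cols) == 0:
        raise ValueError("empty SNP subset")
    Z = dos[:, cols]
    p_hat = Z.mean(axis=0) / 2.0
    bad = (p_hat <= 0) | (p_hat >= 1)
    if bad.any():
        ids = [G.snp_ids[c] for c in cols[bad]]
        raise ValueError(f"monomorphic SNPs in GRM subset: {ids[:5]}")
    Z = (Z - 2 * p_hat) / np.sqrt(2 * p_hat * (1 - p_hat))
    A = Z @ Z.T / len(cols)
    return (A + A.T) / 2.0


def partition_snps(G: GenotypeMatrix, scheme: str = "single") -> np.ndarray:
    """Assign every SNP to exactly one group.

    ``single``: one group.  ``maf_bins:k``: k MAF-quantile bins with
    left-closed boundaries.  ``windows:size``: consecutive position windows
    of the given SNP count.
    """
    p = G.n_snps
    if scheme == "single":
        return np.zeros(p, dtype=int)
    if scheme.startswith("maf_bins"):
        k = int(scheme.split(":")[1]) if ":" in scheme else 2
        if k > p:
            raise ValueError(f"more bins ({k}) than SNPs ({p})")
        maf = G.maf()
        edges = np.quantile(maf, np.linspace(0, 1, k + 1)[1:-1])
        return np.searchsorted(edges, maf, side="right")
    if scheme.startswith("windows"):
        size = int(scheme.split(":")[1]) if ":" in scheme else 1000
        if size < 1:
            raise ValueError("window size must be >= 1")
        return np.arange(p) // size
    raise ValueError(f"unknown partition scheme {scheme!r}")


def kernels_from_partition(G: GenotypeMatrix, labels: np.ndarray, scheme: str = "custom") -> KernelSet:
    groups = np.unique(labels)
    return KernelSet(
        kernels=[grm(G, np.flatnonzero(labels == g)) for g in groups],
        group_labels=[str(g) for g in groups],
        scheme=scheme,
    )


# ---------------------------------------------------------------------------
# REML

def _reml_loglik(y, X, V) -> float:
    n, r = X.shape
    cf = np.linalg.cholesky(V)
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    Py = Vi_y - Vi_X @ beta
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(cf))))
    return -0.5 * (logdet_v + logdet_x + float(y @ Py))


def reml_fit(
    y: np.ndarray,
    X_cov: np.ndarray | None,
    kernels: KernelSet,
    max_iter: int = 200,
    tol: float = 1e-6,
    accelerate: bool = True,
) -> VarianceComponents:
    """EM-REML with average-information acceleration.

    ``X_cov`` holds fixed-effect covariates without an intercept column (an
    intercept is always added).  Variances are floored at 1e-6 times the
    phenotypic variance; convergence is a relative restricted log-likelihood
    change below ``tol``.  With ``accelerate=False`` pure EM steps are taken
    (monotone but slow), which is mainly useful for verification.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.column_stack([np.ones(n)] + ([] if X_cov is None or np.size(X_cov) == 0 else [np.asarray(X_cov, dtype=float)]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    if kernels.n != n:
        raise ValueError("kernel dimension does not match phenotype length")
    K = len(kernels.kernels)
    vary = float(np.var(y, ddof=1))
    floor = 1e-6 * vary

    theta = np.array([0.5 * vary / K] * K + [0.5 * vary])
    mats = list(kernels.kernels) + [np.eye(n)]

    def build_V(th):
        V = np.zeros((n, n))
        for t, A in zip(th, mats):
            V += t * A
        return V

    ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        V = build_V(theta)
        try:
            Vi = np.linalg.inv(V)
        except np.linalg.LinAlgError:
            V += np.eye(n) * 1e-8 * vary
            Vi = np.linalg.inv(V)
        Vi_X = Vi @ X
        XtViX = X.T @ Vi_X
        P = Vi - Vi_X @ np.linalg.solve(XtViX, Vi_X.T)
        Py = P @ y

        PA = [P @ A for A in mats]
        # score: dl/dtheta_k = -0.5 * (tr(P A_k) - y'P A_k P y)
        score = np.array(
            [-0.5 * (np.trace(PA_k) - float(Py @ (A @ Py))) for PA_k, A in zip(PA, mats)]
        )
        # EM update: theta_k <- theta_k + theta_k^2 * (y'P A P y - tr(P A)) / n
        em = np.array(
            [
                t + (t**2) * (float(Py @ (A @ Py)) - np.trace(PA_k)) / n
                for t, PA_k, A in zip(theta, PA, mats)
            ]
        )
        new_theta = None
        AI = np.empty((K + 1, K + 1))
        APy = [A @ Py for A in mats]
        PAPy = [P @ v for v in APy]
        for i in range(K + 1):
            for j in range(i, K + 1):
                AI[i, j] = AI[j, i] = 0.5 * float(APy[i] @ PAPy[j])
        if accelerate and it > 2:
            try:
                step = np.linalg.solve(AI, score)
                cand = theta + step
                if np.all(np.isfinite(cand)):
                    new_theta = np.maximum(cand, floor)
            except np.linalg.LinAlgError:
                new_theta = None
        if new_theta is None:
            new_theta = np.maximum(em, floor)

        new_ll = _reml_loglik(y, X, build_V(new_theta))
        if accelerate and new_ll < ll - 1e-10:
            # AI step decreased the restricted likelihood; fall back to EM
            new_theta = np.maximum(em, floor)
            new_ll = _reml_loglik(y, X, build_V(new_theta))
        delta = abs(new_ll - ll) / (abs(new_ll) + 1.0)
        theta, ll = new_theta, new_ll
        if delta < tol:
            converged = True
            break

    # SEs from the inverse AI matrix at the final estimates
    try:
        AIinv = np.linalg.inv(AI)
        se = np.sqrt(np.clip(np.diag(AIinv), 0, None))
    except np.linalg.LinAlgError:
        AIinv = np.full((K + 1, K + 1), np.nan)
        se = np.full(K + 1, np.nan)

    sg = theta[:K]
    se_total = float(sg.sum() + theta[K])
    h2 = float(sg.sum() / se_total)
    # delta method: h2 = S/(S+e); dh2/dsg_k = e/(S+e)^2, dh2/de = -S/(S+e)^2
    grad = np.empty(K + 1)
    grad[:K] = theta[K] / se_total**2
    grad[K] = -sg.sum() / se_total**2
    var_h2 = float(grad @ AIinv @ grad) if np.isfinite(AIinv).all() else np.nan
    se_h2 = float(np.sqrt(var_h2)) if var_h2 >= 0 else np.nan

    return VarianceComponents(
        sigma2_g=sg.copy(),
        sigma2_e=float(theta[K]),
        h2=h2,
        se_sigma2=se,
        se_h2=se_h2,
        loglik=float(ll),
        iterations=it,
        converged=converged,
        group_labels=list(kernels.group_labels),
    )


# ---------------------------------------------------------------------------
# BLUP prediction

def multiblup_predict(
    vc: VarianceComponents,
    kernels: KernelSet,
    y_train: np.ndarray,
    X_cov: np.ndarray | None,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> np.ndarray:
    """BLUP genetic + fixed-effect score for the test rows.

    Kernels must be computed jointly over all samples; the variance
    components must come from a fit on the training rows only.  With one
    kernel this is exactly GBLUP.
    """
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test indices overlap")
    y_train = np.asarray(y_train, dtype=float)
    n_tr = len(train_idx)
    if len(y_train) != n_tr:
        raise ValueError("y_train length does not match train_idx")

    Xfull = np.ones((kernels.n, 1))
    if X_cov is not None and np.size(X_cov):
        Xfull = np.column_stack([Xfull, np.asarray(X_cov, dtype=float)])
    X_tr, X_te = Xfull[train_idx], Xfull[test_idx]

    V = vc.sigma2_e * np.eye(n_tr)
    for s2, A in zip(vc.sigma2_g, kernels.kernels):
        V += s2 * A[np.ix_(train_idx, train_idx)]
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        Vi = np.linalg.inv(V + np.eye(n_tr) * 1e-8 * float(np.var(y_train) + 1e-12))
    XtViX = X_tr.T @ Vi @ X_tr
    beta = np.linalg.solve(XtViX, X_tr.T @ (Vi @ y_train))
    resid = Vi @ (y_train - X_tr @ beta)

    g_test = np.zeros(len(test_idx))
    for s2, A in zip(vc.sigma2_g, kernels.kernels):
        if s2 > 0:
            g_test += s2 * (A[np.ix_(test_idx, train_idx)] @ resid)
    return X_te @ beta + g_test


def h2_table(vc: VarianceComponents) -> "object":
    """Component / estimate / SE summary frame (one row per kernel + h2)."""
    import pandas as pd

    rows = [
        {"component": f"V(G_{lbl})", "estimate": s2, "se": se}
        for lbl, s2, se in zip(vc.group_labels, vc.sigma2_g, vc.se_sigma2[:-1])
    ]
    rows.append({"component": "V(e)", "estimate": vc.sigma2_e, "se": vc.se_sigma2[-1]})
    rows.append({"component": "h2", "estimate": vc.h2, "se": vc.se_h2})
    return pd.DataFrame(rows)
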