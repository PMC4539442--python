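"""Penalized logistic regression path solvers.

Five penalty families for the binary phenotype model

    (1/n) sum_i [ -y_i x_i'b + log(1 + exp(x_i'b)) ] + sum_j J_lambda(|b_j|)

are provided: ridge J(t) = lam*t^2, lasso J(t) = lam*t, elastic net
J(t) = lam*(a*t + (1-a)*t^2) (note: no 1/2 on the quadratic term, unlike the
glmnet convention), SCAD with derivative J'(t) = min(lam, (a*lam - t)_+ /
(a - 1)), and truncated ridge (ridge estimates with coefficients below a
truncation level a zeroed post hoc).

Convex families are solved by IRLS with cyclic coordinate descent and warm
starts along a descending lambda grid; SCAD by local linear approximation
(a sequence of weighted lasso problems) initialized from the lasso solution
at the same lambda.  Predictors are standardized to unit variance
internally and coefficients reported on the original scale; the recorded
objective refers to the standardized-scale problem, which is the one the
penalty actually acts on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

FAMILIES = ("ridge", "lasso", "elastic_net", "scad", "truncated_ridge")


@dataclass
class PenaltySpec:
    """Penalty family plus tuning grids.

    ``lambda_grid`` may be None (auto-constructed), an explicit descending
    array shared by all mixing values, or a dict mapping mixing value -> grid.
    ``mixing_grid`` holds the elastic-net mixing values in [0, 1], the SCAD
    concavity values (> 2), or the truncated-ridge truncation levels,
    depending on the family; None selects the standard defaults (20 equally
    spaced mixing values, a = 50, 20 log-spaced truncation levels in
    [0.001, 0.01]).
    """

    family: str
    lambda_grid: np.ndarray | dict | None = None
    n_lambda: int = 100
    lambda_ratio: float = 0.01
    mixing_grid: Sequence[float] | None = None
    penalize_covariates: bool = True
    tol: float = 1e-7
    max_sweeps: int = 10_000
    max_irls: int = 200
    lla_max_iter: int = 20

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.mixing_grid is None:
            if self.family == "elastic_net":
                self.mixing_grid = np.linspace(0.0, 1.0, 20)
            elif self.family == "scad":
                self.mixing_grid = np.array([50.0])
            elif self.family == "truncated_ridge":
                self.mixing_grid = np.geomspace(0.001, 0.01, 20)
            else:
                self.mixing_grid = np.array([np.nan])  # placeholder, unused
        else:
            self.mixing_grid = np.asarray(self.mixing_grid, dtype=float)
            if len(self.mixing_grid) == 0:
                raise ValueError("mixing_grid must be nonempty")
        if self.family == "scad" and np.any(self.mixing_grid <= 2):
            raise ValueError("SCAD concavity parameter must exceed 2")
        if self.family == "truncated_ridge" and np.any(self.mixing_grid <= 0):
            raise ValueError("truncation levels must be positive")
        if isinstance(self.lambda_grid, np.ndarray):
            g = self.lambda_grid
            if len(g) == 0 or np.any(g <= 0) or np.any(np.diff(g) >= 0):
                raise ValueError("lambda_grid must be positive and strictly descending")


@dataclass
class PathEntry:
    lam: float
    a: float | None
    beta: np.ndarray        # original scale, intercept first
    beta_std: np.ndarray    # standardized scale, intercept first
    objective: float
    iterations: int
    converged: bool


@dataclass
class FittedModel:
    """One point of a fit path, usable for prediction on new data."""

    family: str
    lam: float
    a: float | None
    beta: np.ndarray  # intercept, covariates, SNPs — original predictor scale
    n_covariates: int
    feature_names: list[str] | None = None

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.beta) - 1:
            raise ValueError(
                f"design has {X.shape[1]} columns, model expects {len(self.beta) - 1}"
                + (f" ({self.feature_names})" if self.feature_names else "")
            )
        return self.beta[0] + X @ self.beta[1:]


@dataclass
class FitPath:
    """Coefficient vectors and diagnostics along the tuning grid."""

    family: str
    entries: list[PathEntry]
    n_covariates: int
    spec: PenaltySpec
    feature_names: list[str] | None = None
    _index: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {(e.lam, e.a): e for e in self.entries}
        if len(self._index) != len(self.entries):
            raise ValueError("duplicate (lambda, a) keys in path")

    def entry(self, lam: float, a: float | None = None) -> PathEntry:
        return self._index[(lam, a)]

    def model(self, lam: float, a: float | None = None) -> FittedModel:
        e = self.entry(lam, a)
        return FittedModel(self.family, e.lam, e.a, e.beta.copy(), self.n_covariates, self.feature_names)

    def models(self) -> list[FittedModel]:
        return [
            FittedModel(self.family, e.lam, e.a, e.beta.copy(), self.n_covariates, self.feature_names)
            for e in self.entries
        ]


# ---------------------------------------------------------------------------
# standardization and grids

def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("NaN in design matrix; impute first")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        raise ValueError(f"zero-variance design columns: {zero.tolist()}")
    return (X - mean) / sd, mean, sd


def _null_probs(y: np.ndarray, Xs_unpen: np.ndarray) -> np.ndarray:
    """Fitted probabilities of the intercept(+unpenalized covariates) model."""
    if Xs_unpen.shape[1] == 0:
        return np.full(len(y), y.mean())
    from .screening import logistic_fit

    b = logistic_fit(Xs_unpen, y)
    return expit(b[0] + Xs_unpen @ b[1:])


def lasso_lambda_max(
    X: np.ndarray,
    y: np.ndarray,
    n_covariates: int = 0,
    penalize_covariates: bool = True,
) -> float:
    """Smallest lambda at which every penalized lasso coefficient is zero.

    From the score of the null (intercept plus any unpenalized covariates)
    fit: lambda_max = max_j |(1/n) x_j'(y - p_null)| over penalized columns
    of the standardized design.
    """
    Xs, _, _ = _standardize(X)
    y = np.asarray(y, dtype=float)
    pen = _penalized_mask(X.shape[1], n_covariates, penalize_covariates)
    p0 = _null_probs(y, Xs[:, ~pen])
    score = np.abs(Xs[:, pen].T @ (y - p0)) / len(y)
    lam = float(score.max()) if score.size else 0.0
    return lam if lam > 0 else 1e-3


def _penalized_mask(p: int, n_covariates: int, penalize_covariates: bool) -> np.ndarray:
    mask = np.ones(p, dtype=bool)
    if not penalize_covariates:
        mask[:n_covariates] = False
    return mask


def lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    family: str = "lasso",
    n_lambda: int = 100,
    ratio: float = 0.01,
    mixing: float | None = None,
    n_covariates: int = 0,
    penalize_covariates: bool = True,
) -> np.ndarray:
    """Descending log-spaced lambda grid for one penalty family.

    lasso/SCAD span [ratio*lam_max, lam_max]; elastic net at mixing a > 0
    rescales by 1/a; ridge, truncated ridge and elastic net at a = 0 extend
    the lasso lam_max upward by one decade (the quadratic penalty never
    zeroes coefficients, so no finite lam_max exists).
    """
    lam_max = lasso_lambda_max(X, y, n_covariates, penalize_covariates)
    if family in ("lasso", "scad"):
        top, bottom = lam_max, ratio * lam_max
    elif family == "elastic_net" and mixing is not None and mixing > 0:
        top, bottom = lam_max / mixing, ratio * lam_max / mixing
    else:  # ridge, truncated_ridge, elastic_net at a=0
        top, bottom = 10.0 * lam_max, ratio * lam_max
    return np.geomspace(top, bottom, n_lambda)


# ---------------------------------------------------------------------------
# objective

def penalty_value(t: np.ndarray, family: str, lam: float, a: float | None) -> np.ndarray:
    """J_lambda(|t|) per coordinate on the standardized scale."""
    t = np.abs(np.asarray(t, dtype=float))
    if family == "ridge":
        return lam * t**2
    if family == "lasso":
        return lam * t
    if family == "elastic_net":
        return lam * (a * t + (1 - a) * t**2)
    if family == "scad":
        mid = (2 * a * lam * t - t**2 - lam**2) / (2 * (a - 1))
        high = lam**2 * (a + 1) / 2
        return np.where(t <= lam, lam * t, np.where(t <= a * lam, mid, high))
    raise ValueError(f"no closed-form penalty for family {family!r}")


def scad_derivative(t: np.ndarray, lam: float, a: float) -> np.ndarray:
    """J'_lambda(t) = min(lam, (a*lam - t)_+ / (a - 1)) for t >= 0."""
    t = np.abs(np.asarray(t, dtype=float))
    return np.minimum(lam, np.maximum(a * lam - t, 0.0) / (a - 1))


def objective(
    Xs: np.ndarray,
    y: np.ndarray,
    beta_std: np.ndarray,
    family: str,
    lam: float,
    a: float | None,
    pen_mask: np.ndarray,
) -> float:
    """Standardized-scale penalized negative log-likelihood (per-sample NLL)."""
    eta = beta_std[0] + Xs @ beta_std[1:]
    nll = float(np.mean(np.logaddexp(0.0, eta) - y * eta))
    return nll + float(penalty_value(beta_std[1:][pen_mask], family, lam, a).sum())


# ---------------------------------------------------------------------------
# IRLS + coordinate descent core

try:
    from numba import njit as _njit

    def _jit(f):
        return _njit(cache=False, fastmath=False)(f)

except ImportError:  # pragma: no cover - numba is a hard speed dependency
    def _jit(f):
        return f


@_jit
def _cd_kernel(Xs, w, z, b0, b, l1, l2, tol, max_sweeps):  # pragma: no cover - jitted
    n, p = Xs.shape
    v = np.zeros(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += w[i] * Xs[i, j] * Xs[i, j]
        v[j] = s / n
    r = z - b0
    for i in range(n):
        acc = 0.0
        for j in range(p):
            acc += Xs[i, j] * b[j]
        r[i] -= acc
    wsum = w.sum()
    sweeps = 0
    while sweeps < max_sweeps:
        sweeps += 1
        # intercept (never penalized)
        d0 = 0.0
        for i in range(n):
            d0 += w[i] * r[i]
        d0 /= wsum
        b0 += d0
        for i in range(n):
            r[i] -= d0
        delta = abs(d0)
        bmax = abs(b0)
        for j in range(p):
            c = 0.0
            for i in range(n):
                c += w[i] * Xs[i, j] * r[i]
            c = c / n + v[j] * b[j]
            if l1[j] > 0.0:
                mag = abs(c) - l1[j]
                new = 0.0 if mag <= 0.0 else np.sign(c) * mag / (v[j] + 2.0 * l2[j])
            else:
                new = c / (v[j] + 2.0 * l2[j])
            d = new - b[j]
            if d != 0.0:
                for i in range(n):
                    r[i] -= d * Xs[i, j]
                b[j] = new
            if abs(d) > delta:
                delta = abs(d)
            if abs(new) > bmax:
                bmax = abs(new)
        if delta < tol or bmax > 100.0:
            # converged, or drifting along a flat (separable) direction --
            # the caller's divergence guard takes over from there
            break
    return b0, sweeps


def _cd_quadratic(
    Xs: np.ndarray,
    w: np.ndarray,
    z: np.ndarray,
    b0: float,
    b: np.ndarray,
    l1: np.ndarray,
    l2: np.ndarray,
    tol: float,
    max_sweeps: int,
) -> tuple[float, np.ndarray, int]:
    """Cyclic coordinate descent on the weighted least-squares surrogate.

    Minimizes (1/2n) sum_i w_i (z_i - b0 - x_i'b)^2 + sum_j l1_j |b_j|
    + l2_j b_j^2, updating ``b`` in place.
    """
    b0, sweeps = _cd_kernel(
        np.asfortranarray(Xs), w, z, float(b0), b, l1, l2, tol, max_sweeps
    )
    return b0, b, sweeps


def _irls_cd(
    Xs: np.ndarray,
    y: np.ndarray,
    l1: np.ndarray,
    l2: np.ndarray,
    b0: float,
    b: np.ndarray,
    tol: float,
    max_sweeps: int,
    max_irls: int,
) -> tuple[float, np.ndarray, int, bool]:
    """Outer IRLS loop around the coordinate-descent surrogate.

    Stops early (flagged unconverged) when coefficients diverge, which
    happens for effectively unpenalized coordinates on separable data.
    """
    it = 0
    converged = False
    for it in range(1, max_irls + 1):
        eta = np.clip(b0 + Xs @ b, -30, 30)
        pr = expit(eta)
        if float(np.max(np.abs(y - pr))) < 1e-3:
            break  # every sample fitted to saturation: separated, no finite MLE
        w = np.clip(pr * (1 - pr), 1e-5, None)
        z = eta + (y - pr) / w
        b0_old, b_old = b0, b.copy()
        b0, b, _ = _cd_quadratic(Xs, w, z, b0, b, l1, l2, tol, max_sweeps)
        if max(abs(b0 - b0_old), float(np.max(np.abs(b - b_old), initial=0.0))) < tol * 10:
            converged = True
            break
        if max(abs(b0), float(np.max(np.abs(b), initial=0.0))) > 60.0:
            break  # separation: likelihood flat, coefficients unbounded
    return b0, b, it, converged


def _irls_ridge(
    Xs: np.ndarray,
    y: np.ndarray,
    lam: float,
    pen_mask: np.ndarray,
    b0: float,
    b: np.ndarray,
    tol: float,
    max_irls: int,
) -> tuple[float, np.ndarray, int, bool]:
    """Direct Newton/IRLS solve for the pure quadratic (ridge) penalty."""
    n, p = Xs.shape
    D = np.column_stack([np.ones(n), Xs])
    pen = np.concatenate([[0.0], np.where(pen_mask, 2.0 * lam, 0.0)])
    beta = np.concatenate([[b0], b])
    converged = False
    it = 0
    for it in range(1, max_irls + 1):
        eta = np.clip(D @ beta, -30, 30)
        pr = expit(eta)
        w = np.clip(pr * (1 - pr), 1e-5, None)
        z = eta + (y - pr) / w
        H = (D * w[:, None]).T @ D / n + np.diag(pen)
        rhs = (D * w[:, None]).T @ z / n
        new = np.linalg.solve(H, rhs)
        delta = float(np.max(np.abs(new - beta)))
        beta = new
        if delta < tol * 10:
            converged = True
            break
    return float(beta[0]), beta[1:], it, converged


# ---------------------------------------------------------------------------
# path fitting

def _resolve_grid(spec: PenaltySpec, X, y, a: float | None, n_covariates: int) -> np.ndarray:
    if isinstance(spec.lambda_grid, dict):
        key = a if a is not None else "default"
        if key in spec.lambda_grid:
            return np.asarray(spec.lambda_grid[key], dtype=float)
        if "default" in spec.lambda_grid:
            return np.asarray(spec.lambda_grid["default"], dtype=float)
        return np.asarray(next(iter(spec.lambda_grid.values())), dtype=float)
    if spec.lambda_grid is not None:
        return np.asarray(spec.lambda_grid, dtype=float)
    return lambda_grid(
        X,
        y,
        family=spec.family,
        n_lambda=spec.n_lambda,
        ratio=spec.lambda_ratio,
        mixing=a,
        n_covariates=n_covariates,
        penalize_covariates=spec.penalize_covariates,
    )


def fit_path(
    X: np.ndarray,
    y: np.ndarray,
    spec: PenaltySpec,
    n_covariates: int = 0,
    feature_names: list[str] | None = None,
) -> FitPath:
    """Fit the full coefficient path for one penalty family.

    X holds environmental covariates (first ``n_covariates`` columns) then
    SNP dosages, without an intercept column; y is 0/1.  The intercept is
    never penalized; covariates are penalized unless the spec opts out.
    """
    y = np.asarray(y, dtype=float)
    if not np.isin(y, [0, 1]).all():
        raise ValueError("y must be 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    Xs, mean, sd = _standardize(X)
    p = Xs.shape[1]
    pen_mask = _penalized_mask(p, n_covariates, spec.penalize_covariates)

    if spec.family == "truncated_ridge":
        ridge_spec = replace(spec, family="ridge", mixing_grid=None, lambda_grid=spec.lambda_grid)
        ridge_path = fit_path(X, y, ridge_spec, n_covariates, feature_names)
        return truncate_ridge_path(ridge_path, spec.mixing_grid)

    entries: list[PathEntry] = []
    mixing_values: list[float | None]
    if spec.family in ("ridge", "lasso"):
        mixing_values = [None]
    else:
        mixing_values = [float(a) for a in spec.mixing_grid]

    for a in mixing_values:
        grid = _resolve_grid(spec, X, y, a, n_covariates)
        b0, b = float(np.log(y.mean() / (1 - y.mean()))), np.zeros(p)
        lasso_warm = (b0, b.copy())  # for SCAD's lasso initialization chain
        for lam in grid:
            if spec.family == "ridge" or (spec.family == "elastic_net" and a == 0.0):
                fam_eff = "ridge"
                b0, b, it, conv = _irls_ridge(
                    Xs, y, lam, pen_mask, b0, b, spec.tol, spec.max_irls
                )
            elif spec.family == "lasso" or (spec.family == "elastic_net" and a == 1.0):
                fam_eff = spec.family
                l1 = np.where(pen_mask, lam, 0.0)
                l2 = np.zeros(p)
                b0, b, it, conv = _irls_cd(
                    Xs, y, l1, l2, b0, b, spec.tol, spec.max_sweeps, spec.max_irls
                )
            elif spec.family == "elastic_net":
                fam_eff = "elastic_net"
                l1 = np.where(pen_mask, lam * a, 0.0)
                l2 = np.where(pen_mask, lam * (1 - a), 0.0)
                b0, b, it, conv = _irls_cd(
                    Xs, y, l1, l2, b0, b, spec.tol, spec.max_sweeps, spec.max_irls
                )
            elif spec.family == "scad":
                fam_eff = "scad"
                # lasso warm-start chain at this lambda
                l1 = np.where(pen_mask, lam, 0.0)
                l2 = np.zeros(p)
                lb0, lb, _, _ = _irls_cd(
                    Xs, y, l1, l2, lasso_warm[0], lasso_warm[1].copy(),
                    spec.tol, spec.max_sweeps, spec.max_irls,
                )
                lasso_warm = (lb0, lb.copy())
                b0, b = lb0, lb.copy()
                it, conv = 0, False
                for _ in range(spec.lla_max_iter):
                    wts = scad_derivative(np.abs(b), lam, a)
                    l1 = np.where(pen_mask, wts, 0.0)
                    prev0, prev = b0, b.copy()
                    b0, b, it_i, conv = _irls_cd(
                        Xs, y, l1, l2, b0, b, spec.tol, spec.max_sweeps, spec.max_irls
                    )
                    it += it_i
                    if max(abs(b0 - prev0), float(np.max(np.abs(b - prev), initial=0.0))) < 1e-6:
                        break
                    if not conv:
                        break  # inner solver stalled or diverged; keep flagged entry
            else:  # pragma: no cover
                raise AssertionError(spec.family)

            beta_std = np.concatenate([[b0], b])
            beta_orig = np.empty_like(beta_std)
            beta_orig[1:] = beta_std[1:] / sd
            beta_orig[0] = beta_std[0] - float((beta_std[1:] / sd) @ mean)
            obj = objective(Xs, y, beta_std, fam_eff, lam, a, pen_mask)
            entries.append(
                PathEntry(float(lam), a, beta_orig, beta_std, obj, it, conv)
            )
    return FitPath(spec.family, entries, n_covariates, spec, feature_names)


def truncate_ridge_path(ridge_path: FitPath, a_grid: Sequence[float]) -> FitPath:
    """Truncated ridge: zero penalized ridge coefficients with |b_j| < a.

    Truncation acts on the original-scale coefficients; coefficients at or
    above the level — and the intercept — are kept intact.
    """
    a_grid = np.asarray(a_grid, dtype=float)
    if np.any(a_grid <= 0):
        raise ValueError("truncation levels must be positive")
    spec = ridge_path.spec
    pen_mask = _penalized_mask(
        len(ridge_path.entries[0].beta) - 1,
        ridge_path.n_covariates,
        spec.penalize_covariates,
    )
    entries = []
    for e in ridge_path.entries:
        for a in a_grid:
            beta = e.beta.copy()
            kill = pen_mask & (np.abs(beta[1:]) < a)
            beta[1:][kill] = 0.0
            beta_std = e.beta_std.copy()
            beta_std[1:][kill] = 0.0
            entries.append(
                PathEntry(e.lam, float(a), beta, beta_std, np.nan, e.iterations, e.converged)
            )
    return FitPath(
        "truncated_ridge",
        entries,
        ridge_path.n_covariates,
        replace(spec, family="truncated_ridge", mixing_grid=a_grid),
        ridge_path.feature_names,
    )


# ---------------------------------------------------------------------------
# prediction, tuning, complexity

def predict_prob(model: FittedModel, X_new: np.ndarray) -> np.ndarray:
    """Per-sample probability 1 / (1 + exp(-x'b))."""
    return expit(model.linear_predictor(X_new))


def nonzero_snps(model: FittedModel) -> int:
    """Number of SNP coefficients that are exactly nonzero.

    The intercept and environmental covariates are excluded; for truncated
    ridge the count is taken after truncation.
    """
    snp_beta = model.beta[1 + model.n_covariates :]
    return int(np.count_nonzero(snp_beta))


@dataclass
class TuningResult:
    lam: float
    a: float | None
    model: FittedModel
    cv_table: "np.ndarray | object"  # pandas DataFrame of per-grid-point CV AUC
    rule: str


def select_tuning(
    X: np.ndarray,
    y: np.ndarray,
    spec: PenaltySpec,
    n_covariates: int = 0,
    rule: str = "max_auc",
    inner_k: int = 5,
    seed: int = 0,
) -> TuningResult:
    """Inner stratified k-fold CV over the tuning grid on training data.

    ``max_auc`` returns the grid point with the highest mean validation AUC
    (ties broken toward the sparser / larger-lambda entry); ``one_se``
    returns the sparsest grid point whose mean AUC is within one standard
    error of the best.
    """
    import pandas as pd

    from .evaluation import auc, stratified_folds

    if rule not in ("max_auc", "one_se"):
        raise ValueError(f"unknown tuning rule {rule!r}")
    y = np.asarray(y, dtype=int)
    full_path = fit_path(X, y, spec, n_covariates)
    keys = [(e.lam, e.a) for e in full_path.entries]
    grids: dict = {}
    for lam, a in keys:
        grids.setdefault(a if a is not None else "default", []).append(lam)
    fixed = replace(
        spec,
        lambda_grid={k: np.asarray(sorted(set(v), reverse=True)) for k, v in grids.items()},
        mixing_grid=None if spec.family in ("ridge", "lasso") else spec.mixing_grid,
    )

    folds = None
    for attempt in range(3):
        try:
            cand = stratified_folds(y, k=inner_k, seed=seed + attempt)
        except ValueError:
            continue
        if all(len(np.unique(y[cand != f])) == 2 for f in range(inner_k)):
            folds = cand
            break
    if folds is None:
        raise ValueError("could not build inner CV folds with both classes present")

    scores = {key: [] for key in keys}
    for f in range(inner_k):
        tr = np.flatnonzero(folds != f)
        va = np.flatnonzero(folds == f)
        path_f = fit_path(X[tr], y[tr], fixed, n_covariates)
        for e in path_f.entries:
            m = FittedModel(path_f.family, e.lam, e.a, e.beta, n_covariates)
            scores[(e.lam, e.a)].append(auc(predict_prob(m, X[va]), y[va]))
    table = pd.DataFrame(
        [
            {
                "lambda": lam,
                "a": a,
                "mean_auc": float(np.mean(scores[(lam, a)])),
                "se_auc": float(np.std(scores[(lam, a)], ddof=1) / np.sqrt(inner_k)),
            }
            for (lam, a) in keys
        ]
    )

    mean_auc = table["mean_auc"].to_numpy()
    best_i = int(np.argmax(mean_auc))
    if rule == "max_auc":
        chosen = best_i
    else:
        cutoff = mean_auc[best_i] - table["se_auc"].iloc[best_i]
        cand = np.flatnonzero(mean_auc >= cutoff)
        nz = np.array([nonzero_snps(full_path.models()[i]) for i in cand])
        lam_of = np.array([keys[i][0] for i in cand])
        order = np.lexsort((-lam_of, nz))  # sparsest, then larger lambda
        chosen = int(cand[order[0]])
    lam, a = keys[chosen]
    return TuningResult(lam, a, full_path.model(lam, a), table, rule)
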