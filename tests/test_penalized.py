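"""Path solvers: oracle equivalence, KKT conditions, family identities."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from penrisk.penalized import (
    FittedModel,
    PenaltySpec,
    _standardize,
    fit_path,
    lambda_grid,
    lasso_lambda_max,
    nonzero_snps,
    objective,
    predict_prob,
    scad_derivative,
    select_tuning,
    truncate_ridge_path,
)

TIGHT = dict(tol=1e-11, max_irls=500)


def standardized_instance(seed, n=40, p=4, signal=1.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = signal * rng.standard_normal(p)
    y = (rng.random(n) < expit(X @ beta)).astype(float)
    if y.sum() in (0, len(y)):
        y[0] = 1 - y[0]
    Xs, _, _ = _standardize(X)
    return Xs, y


def nll_grad(Xs, y, beta):
    """Gradient of the (1/n) logistic negative log-likelihood."""
    eta = beta[0] + Xs @ beta[1:]
    p = expit(eta)
    n = len(y)
    return np.concatenate([[np.mean(p - y)], Xs.T @ (p - y) / n])


# ---------------------------------------------------------------------------
# lambda grid

def test_default_grid_has_100_points_and_descends(rng):
    X = rng.standard_normal((50, 8))
    y = rng.permutation(np.r_[np.zeros(25), np.ones(25)])
    g = lambda_grid(X, y)
    assert len(g) == 100
    assert np.all(np.diff(g) < 0)
    assert np.all(g > 0)


def test_grid_rejects_zero_variance_columns(rng):
    X = rng.standard_normal((30, 3))
    X[:, 1] = 2.0
    y = np.r_[np.zeros(15), np.ones(15)]
    with pytest.raises(ValueError, match="1"):
        lambda_grid(X, y)


def test_lasso_all_zero_at_lambda_max_with_null_intercept():
    Xs, y = standardized_instance(0)
    lam_max = lasso_lambda_max(Xs, y)
    spec = PenaltySpec(family="lasso", lambda_grid=np.array([2 * lam_max, lam_max]), **TIGHT)
    path = fit_path(Xs, y, spec)
    for e in path.entries:
        assert np.all(e.beta[1:] == 0.0)
        n_a, n_u = y.sum(), (1 - y).sum()
        assert e.beta[0] == pytest.approx(np.log(n_a / n_u), abs=1e-6)


# ---------------------------------------------------------------------------
# oracle equivalence (generic numerical minimizer of the penalized NLL)

def oracle_min(Xs, y, family, lam, a, n_starts=4, seed=0):
    rng = np.random.default_rng(seed)
    p = Xs.shape[1]
    pen_mask = np.ones(p, dtype=bool)

    def obj(b):
        return objective(Xs, y, b, family, lam, a, pen_mask)

    best = np.inf
    for s in range(n_starts):
        x0 = np.zeros(p + 1) if s == 0 else 0.5 * rng.standard_normal(p + 1)
        r = minimize(obj, x0, method="Nelder-Mead",
                     options={"maxiter": 40000, "xatol": 1e-10, "fatol": 1e-13})
        best = min(best, r.fun)
    return best


@pytest.mark.parametrize(
    "family,mixing",
    [("lasso", None), ("ridge", None), ("elastic_net", [0.3]), ("scad", [50.0])],
)
def test_objective_matches_generic_minimizer(family, mixing):
    for seed in range(5):
        Xs, y = standardized_instance(seed, n=35, p=4)
        spec = PenaltySpec(family=family, n_lambda=5, mixing_grid=mixing, **TIGHT)
        path = fit_path(Xs, y, spec)
        for e in path.entries:
            fam = family
            ref = oracle_min(Xs, y, fam, e.lam, e.a, seed=seed)
            assert e.objective <= ref + 1e-4, (family, seed, e.lam)


# ---------------------------------------------------------------------------
# KKT / stationarity

def test_lasso_kkt_residuals():
    for seed in range(5):
        Xs, y = standardized_instance(seed, n=50, p=5)
        spec = PenaltySpec(family="lasso", n_lambda=8, **TIGHT)
        path = fit_path(Xs, y, spec)
        for e in path.entries:
            g = nll_grad(Xs, y, e.beta_std)
            assert abs(g[0]) < 1e-6  # intercept stationarity
            for j in range(5):
                bj, gj = e.beta_std[1 + j], g[1 + j]
                if bj != 0:
                    assert abs(gj + e.lam * np.sign(bj)) < 1e-6
                else:
                    assert abs(gj) <= e.lam + 1e-6


def test_elastic_net_kkt_residuals():
    a = 0.4
    for seed in range(3):
        Xs, y = standardized_instance(seed + 7, n=50, p=5)
        spec = PenaltySpec(family="elastic_net", n_lambda=6, mixing_grid=[a], **TIGHT)
        path = fit_path(Xs, y, spec)
        for e in path.entries:
            g = nll_grad(Xs, y, e.beta_std)
            for j in range(5):
                bj, gj = e.beta_std[1 + j], g[1 + j]
                if bj != 0:
                    resid = gj + e.lam * a * np.sign(bj) + 2 * e.lam * (1 - a) * bj
                    assert abs(resid) < 1e-6
                else:
                    assert abs(gj) <= e.lam * a + 1e-6


def test_ridge_gradient_norm_small():
    for seed in range(3):
        Xs, y = standardized_instance(seed + 3, n=40, p=5)
        spec = PenaltySpec(family="ridge", n_lambda=6, **TIGHT)
        path = fit_path(Xs, y, spec)
        for e in path.entries:
            g = nll_grad(Xs, y, e.beta_std) + np.concatenate(
                [[0.0], 2 * e.lam * e.beta_std[1:]]
            )
            assert np.linalg.norm(g) < 1e-6


def test_scad_local_optimality_under_perturbation():
    Xs, y = standardized_instance(11, n=40, p=4)
    spec = PenaltySpec(family="scad", n_lambda=5, mixing_grid=[50.0], **TIGHT)
    path = fit_path(Xs, y, spec)
    pen_mask = np.ones(4, dtype=bool)
    for e in path.entries:
        base = objective(Xs, y, e.beta_std, "scad", e.lam, e.a, pen_mask)
        for j in range(5):
            for delta in (1e-3, -1e-3):
                pert = e.beta_std.copy()
                pert[j] += delta
                assert objective(Xs, y, pert, "scad", e.lam, e.a, pen_mask) >= base - 1e-9


# ---------------------------------------------------------------------------
# family identities

def test_unpenalized_limit_matches_mle():
    Xs, y = standardized_instance(21, n=30, p=3)
    spec = PenaltySpec(family="lasso", lambda_grid=np.array([1e-2, 1e-6]), **TIGHT)
    path = fit_path(Xs, y, spec)
    e = path.entries[-1]

    def nll(b):
        eta = b[0] + Xs @ b[1:]
        return np.mean(np.logaddexp(0, eta) - y * eta)

    ref = minimize(nll, np.zeros(4), method="BFGS", tol=1e-14)
    np.testing.assert_allclose(e.beta_std, ref.x, atol=1e-4)


def test_elastic_net_limits_reproduce_lasso_and_ridge():
    Xs, y = standardized_instance(5, n=45, p=5)
    grid = lambda_grid(Xs, y, family="lasso", n_lambda=6)
    enet1 = fit_path(Xs, y, PenaltySpec("elastic_net", lambda_grid=grid, mixing_grid=[1.0], **TIGHT))
    lasso = fit_path(Xs, y, PenaltySpec("lasso", lambda_grid=grid, **TIGHT))
    for e1, e2 in zip(enet1.entries, lasso.entries):
        np.testing.assert_allclose(e1.beta, e2.beta, atol=1e-6)

    rgrid = lambda_grid(Xs, y, family="ridge", n_lambda=6)
    enet0 = fit_path(Xs, y, PenaltySpec("elastic_net", lambda_grid=rgrid, mixing_grid=[0.0], **TIGHT))
    ridge = fit_path(Xs, y, PenaltySpec("ridge", lambda_grid=rgrid, **TIGHT))
    for e1, e2 in zip(enet0.entries, ridge.entries):
        np.testing.assert_allclose(e1.beta, e2.beta, atol=1e-6)


class TestTruncatedRidge:
    @pytest.fixture
    def ridge_path(self):
        Xs, y = standardized_instance(9, n=50, p=6)
        return fit_path(Xs, y, PenaltySpec("ridge", n_lambda=4, **TIGHT))

    def test_below_smallest_coefficient_is_identity(self, ridge_path):
        min_nz = min(
            np.abs(e.beta[1:])[np.abs(e.beta[1:]) > 0].min() for e in ridge_path.entries
        )
        tr = truncate_ridge_path(ridge_path, [min_nz / 2])
        for e_tr, e_r in zip(tr.entries, ridge_path.entries):
            np.testing.assert_array_equal(e_tr.beta, e_r.beta)

    def test_above_largest_zeroes_everything_but_intercept(self, ridge_path):
        big = max(np.abs(e.beta[1:]).max() for e in ridge_path.entries) * 2
        tr = truncate_ridge_path(ridge_path, [big])
        for e_tr, e_r in zip(tr.entries, ridge_path.entries):
            assert np.all(e_tr.beta[1:] == 0)
            assert e_tr.beta[0] == e_r.beta[0]

    def test_survivor_count_and_monotonicity(self, ridge_path):
        levels = np.geomspace(1e-4, 1.0, 8)
        tr = truncate_ridge_path(ridge_path, levels)
        for e_r in ridge_path.entries:
            counts = []
            for a in levels:
                e_tr = tr.entry(e_r.lam, a)
                expected = int((np.abs(e_r.beta[1:]) >= a).sum())
                got = int(np.count_nonzero(e_tr.beta[1:]))
                assert got == expected
                counts.append(got)
            assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))

    def test_nonpositive_level_rejected(self, ridge_path):
        with pytest.raises(ValueError):
            truncate_ridge_path(ridge_path, [0.0])


def test_scad_unbiasedness_orthonormal_limit():
    """Coefficients with |MLE| > a*lam escape the penalty entirely."""
    rng = np.random.default_rng(17)
    n = 4000
    x = rng.standard_normal(n)
    y = (rng.random(n) < expit(1.2 * x)).astype(float)
    Xs, _, _ = _standardize(x.reshape(-1, 1))
    lam = 0.02  # a*lam = 1 < |MLE| ~ 1.2
    spec = PenaltySpec("scad", lambda_grid=np.array([lam]), mixing_grid=[50.0], **TIGHT)
    e = fit_path(Xs, y, spec).entries[0]

    def nll(b):
        eta = b[0] + Xs @ b[1:]
        return np.mean(np.logaddexp(0, eta) - y * eta)

    mle = minimize(nll, np.zeros(2), method="BFGS", tol=1e-12).x
    assert abs(mle[1]) > 50.0 * lam
    np.testing.assert_allclose(e.beta_std, mle, atol=1e-5)


def test_large_lambda_predictions_are_case_fraction():
    Xs, y = standardized_instance(31, n=60, p=5)
    for family in ("lasso", "ridge", "elastic_net", "scad"):
        mix = {"elastic_net": [0.5], "scad": [50.0]}.get(family)
        # ridge shrinks towards (not onto) zero, so push lambda much higher
        lam = 1e5 if family == "ridge" else 50.0
        spec = PenaltySpec(family, lambda_grid=np.array([lam]), mixing_grid=mix, **TIGHT)
        e = fit_path(Xs, y, spec).entries[0]
        assert np.abs(e.beta[1:]).max() < 1e-5
        m = FittedModel(family, e.lam, e.a, e.beta, 0)
        np.testing.assert_allclose(predict_prob(m, Xs), y.mean(), atol=1e-4)


def test_scaling_round_trip_reproduces_predictions(rng):
    # fitting on rescaled predictors must give identical probabilities
    n, p = 80, 6
    X = rng.standard_normal((n, p)) * np.array([1, 10, 0.1, 5, 2, 0.5])
    y = (rng.random(n) < expit(X[:, 0] - 0.2 * X[:, 1])).astype(float)
    scale = np.array([2.0, 0.5, 10.0, 1.0, 0.1, 3.0])
    grid = lambda_grid(X, y, family="lasso", n_lambda=5)
    p1 = fit_path(X, y, PenaltySpec("lasso", lambda_grid=grid, **TIGHT))
    p2 = fit_path(X * scale, y, PenaltySpec("lasso", lambda_grid=grid, **TIGHT))
    for e1, e2 in zip(p1.entries, p2.entries):
        m1 = FittedModel("lasso", e1.lam, None, e1.beta, 0)
        m2 = FittedModel("lasso", e2.lam, None, e2.beta, 0)
        np.testing.assert_allclose(
            predict_prob(m1, X), predict_prob(m2, X * scale), atol=1e-7
        )


def test_warm_start_path_continuity():
    Xs, y = standardized_instance(13, n=100, p=8)
    path = fit_path(Xs, y, PenaltySpec("lasso", n_lambda=50, **TIGHT))
    betas = np.array([e.beta_std for e in path.entries])
    steps = np.abs(np.diff(betas, axis=0)).max(axis=1)
    assert steps.max() < 0.5  # no jumps between adjacent grid points


# ---------------------------------------------------------------------------
# prediction / complexity / tuning

def test_predict_prob_worked_sigmoid():
    m = FittedModel("lasso", 0.1, None, np.array([0.5, 1.0, -2.0]), 0)
    X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.5]])
    eta = np.array([0.5, -0.5, 1.5])
    np.testing.assert_allclose(predict_prob(m, X), 1 / (1 + np.exp(-eta)), atol=1e-12)


def test_predict_prob_column_mismatch():
    m = FittedModel("lasso", 0.1, None, np.array([0.0, 1.0]), 0)
    with pytest.raises(ValueError, match="columns"):
        predict_prob(m, np.zeros((3, 2)))


def test_nonzero_snps_excludes_covariates_and_intercept():
    beta = np.array([1.0, 0.7, 0.0, 0.3, 0.0, -0.2])  # intercept + 2 covars + 3 SNPs
    m = FittedModel("lasso", 0.1, None, beta, 2)
    assert nonzero_snps(m) == 2


def test_ridge_keeps_all_snps(rng):
    Xs, y = standardized_instance(41, n=60, p=10)
    e = fit_path(Xs, y, PenaltySpec("ridge", n_lambda=3, **TIGHT)).entries[-1]
    assert nonzero_snps(FittedModel("ridge", e.lam, None, e.beta, 0)) == 10


class TestSelectTuning:
    def make_data(self, seed=0, n=120, p=10):
        rng = np.random.default_rng(seed)
        X = rng.binomial(2, 0.3, (n, p)).astype(float)
        eta = 0.8 * (X[:, 0] - X[:, 0].mean()) - 0.6 * (X[:, 1] - X[:, 1].mean())
        y = (rng.random(n) < expit(eta)).astype(int)
        if y.sum() < 10 or y.sum() > n - 10:
            return self.make_data(seed + 1, n, p)
        return X, y

    def test_single_point_grid_returned(self):
        X, y = self.make_data()
        spec = PenaltySpec("lasso", lambda_grid=np.array([0.05]))
        res = select_tuning(X, y, spec, seed=3)
        assert res.lam == 0.05

    def test_max_auc_is_argmax_and_deterministic(self):
        X, y = self.make_data(5)
        spec = PenaltySpec("lasso", n_lambda=8)
        r1 = select_tuning(X, y, spec, rule="max_auc", seed=11)
        r2 = select_tuning(X, y, spec, rule="max_auc", seed=11)
        assert (r1.lam, r1.a) == (r2.lam, r2.a)
        best = r1.cv_table["mean_auc"].max()
        chosen = r1.cv_table.loc[
            (r1.cv_table["lambda"] == r1.lam), "mean_auc"
        ].max()
        assert chosen == pytest.approx(best)

    def test_one_se_at_least_as_sparse_as_max_auc(self):
        X, y = self.make_data(8)
        spec = PenaltySpec("lasso", n_lambda=10)
        r_max = select_tuning(X, y, spec, rule="max_auc", seed=2)
        r_1se = select_tuning(X, y, spec, rule="one_se", seed=2)
        assert nonzero_snps(r_1se.model) <= nonzero_snps(r_max.model)
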