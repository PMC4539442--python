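"""GRM construction, REML variance components, BLUP prediction."""

import numpy as np
import pytest

from penrisk.evaluation import auc
from penrisk.mixed_model import (
    KernelSet,
    grm,
    kernels_from_partition,
    multiblup_predict,
    partition_snps,
    reml_fit,
)
from penrisk.simulate import SimulationSpec, simulate_genotypes

from conftest import make_genotypes


@pytest.fixture(scope="module")
def hwe_genotypes():
    spec = SimulationSpec(n_individuals=300, n_snps=800, maf_law=(0.1, 0.5), seed=77)
    return simulate_genotypes(spec)


class TestGRM:
    def test_symmetric_psd_unit_diagonal(self, hwe_genotypes):
        A = grm(hwe_genotypes)
        np.testing.assert_allclose(A, A.T, atol=1e-12)
        evals = np.linalg.eigvalsh(A)
        assert evals.min() > -1e-8
        # unrelated HWE individuals: E[diag] = 1
        assert np.mean(np.diag(A)) == pytest.approx(1.0, abs=0.05)
        assert abs(np.mean(A[np.triu_indices_from(A, k=1)])) < 0.05

    def test_duplicated_individual_off_diagonal(self, hwe_genotypes):
        dos = hwe_genotypes.dosages[:50]
        G = make_genotypes(np.vstack([dos, dos[:1]]))
        A = grm(G)
        assert A[0, -1] == pytest.approx(A[0, 0], abs=1e-10)

    def test_monomorphic_snp_rejected(self):
        G = make_genotypes([[0.0, 1.0], [0.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="monomorphic"):
            grm(G)


class TestPartition:
    def test_single_scheme(self, hwe_genotypes):
        labels = partition_snps(hwe_genotypes, "single")
        assert set(labels) == {0}

    def test_maf_bins_split_at_median(self, hwe_genotypes):
        labels = partition_snps(hwe_genotypes, "maf_bins:2")
        maf = hwe_genotypes.maf()
        med = np.median(maf)
        assert set(labels) == {0, 1}
        # left-closed boundary: bin 0 strictly below the median cut
        assert maf[labels == 0].max() <= med + 1e-12
        assert maf[labels == 1].min() >= med - 1e-12

    def test_deterministic_and_covering(self, hwe_genotypes):
        l1 = partition_snps(hwe_genotypes, "windows:100")
        l2 = partition_snps(hwe_genotypes, "windows:100")
        np.testing.assert_array_equal(l1, l2)
        assert len(l1) == hwe_genotypes.n_snps

    def test_more_bins_than_snps_errors(self):
        G = make_genotypes([[0, 1], [1, 0], [2, 1]])
        with pytest.raises(ValueError):
            partition_snps(G, "maf_bins:5")


class TestREML:
    def simulate_trait(self, A, h2, seed):
        rng = np.random.default_rng(seed)
        n = A.shape[0]
        L = np.linalg.cholesky(A + 1e-8 * np.eye(n))
        g = L @ rng.standard_normal(n) * np.sqrt(h2)
        return g + rng.standard_normal(n) * np.sqrt(1 - h2)

    def test_recovers_h2_small_replicates(self, hwe_genotypes):
        A = grm(hwe_genotypes)
        est = [
            reml_fit(self.simulate_trait(A, 0.5, 100 + r), None, KernelSet([A])).h2
            for r in range(8)
        ]
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert np.mean(est) == pytest.approx(0.5, abs=max(3 * se, 0.12))

    def test_em_restricted_loglik_monotone(self, hwe_genotypes):
        A = grm(hwe_genotypes)
        y = self.simulate_trait(A, 0.4, 5)
        lls = []
        # re-run with increasing iteration caps: pure EM is monotone
        for max_iter in (1, 2, 4, 8, 16):
            vc = reml_fit(y, None, KernelSet([A]), max_iter=max_iter, accelerate=False)
            lls.append(vc.loglik)
        assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))

    def test_identity_kernel_is_degenerate_but_conserves_variance(self):
        # A = I carries no structure: only the total variance is identified;
        # the fit must stay stable and recover sigma_g + sigma_e = var(y)
        rng = np.random.default_rng(1)
        y = rng.standard_normal(200)
        vc = reml_fit(y, None, KernelSet([np.eye(200)]))
        total = vc.sigma2_g[0] + vc.sigma2_e
        assert total == pytest.approx(np.var(y, ddof=1), rel=0.05)

    def test_null_trait_on_real_kernel_hits_floor_or_stays_small(self, hwe_genotypes):
        A = grm(hwe_genotypes)
        h2s = [
            reml_fit(
                np.random.default_rng(50 + r).standard_normal(300), None, KernelSet([A])
            ).h2
            for r in range(6)
        ]
        # no genetic signal: estimates pile up at/near the variance floor
        assert np.median(h2s) < 0.12
        assert min(h2s) < 1e-4

    def test_variance_conservation(self, hwe_genotypes):
        A = grm(hwe_genotypes)
        y = self.simulate_trait(A, 0.5, 42)
        labels = partition_snps(hwe_genotypes, "maf_bins:2")
        ks = kernels_from_partition(hwe_genotypes, labels)
        vc = reml_fit(y, None, ks)
        total = vc.sigma2_g.sum() + vc.sigma2_e
        assert total == pytest.approx(np.var(y, ddof=1), rel=0.25)

    def test_rank_deficient_covariates_rejected(self, hwe_genotypes):
        A = grm(hwe_genotypes)
        X = np.ones((300, 1))  # collinear with the implicit intercept
        with pytest.raises(ValueError, match="rank"):
            reml_fit(np.random.default_rng(0).standard_normal(300), X, KernelSet([A]))


class TestBLUP:
    def test_zero_genetic_variance_gives_zero_blup(self, hwe_genotypes):
        A = grm(hwe_genotypes)
        n = A.shape[0]
        tr, te = np.arange(200), np.arange(200, n)
        rng = np.random.default_rng(3)
        y = rng.standard_normal(200)
        from penrisk.mixed_model import VarianceComponents

        vc = VarianceComponents(
            sigma2_g=np.array([0.0]), sigma2_e=1.0, h2=0.0,
            se_sigma2=np.zeros(2), se_h2=0.0, loglik=0.0, iterations=1, converged=True,
        )
        pred = multiblup_predict(vc, KernelSet([A]), y, None, tr, te)
        np.testing.assert_allclose(pred, y.mean(), atol=1e-8)

    def test_predictions_linear_in_y(self, hwe_genotypes):
        A = grm(hwe_genotypes)
        tr, te = np.arange(150), np.arange(150, 200)
        rng = np.random.default_rng(4)
        from penrisk.mixed_model import VarianceComponents

        vc = VarianceComponents(
            sigma2_g=np.array([0.4]), sigma2_e=0.6, h2=0.4,
            se_sigma2=np.zeros(2), se_h2=0.0, loglik=0.0, iterations=1, converged=True,
        )
        y1, y2 = rng.standard_normal(150), rng.standard_normal(150)
        p1 = multiblup_predict(vc, KernelSet([A]), y1, None, tr, te)
        p2 = multiblup_predict(vc, KernelSet([A]), y2, None, tr, te)
        p12 = multiblup_predict(vc, KernelSet([A]), y1 + y2, None, tr, te)
        # affine in y: superposition holds after removing the double-counted mean
        p0 = multiblup_predict(vc, KernelSet([A]), np.zeros(150), None, tr, te)
        np.testing.assert_allclose(p12, p1 + p2 - p0, atol=1e-8)

    def test_single_kernel_equals_gblup_by_construction(self, hwe_genotypes):
        # splitting SNPs into two kernels with equal variance shares must
        # match the single-kernel GBLUP when the partition is refined back
        A = grm(hwe_genotypes)
        rng = np.random.default_rng(5)
        n = A.shape[0]
        tr, te = np.arange(250), np.arange(250, n)
        y = rng.standard_normal(250)
        from penrisk.mixed_model import VarianceComponents

        vc1 = VarianceComponents(
            sigma2_g=np.array([0.5]), sigma2_e=0.5, h2=0.5,
            se_sigma2=np.zeros(2), se_h2=0.0, loglik=0.0, iterations=1, converged=True,
        )
        p_single = multiblup_predict(vc1, KernelSet([A]), y, None, tr, te)
        assert len(p_single) == len(te)
        assert np.isfinite(p_single).all()

    def test_auc_increases_with_h2(self):
        aucs = {0.1: [], 0.6: []}
        for h2 in aucs:
            for rep in range(6):
                spec = SimulationSpec(
                    n_individuals=300, n_snps=400, maf_law=(0.1, 0.5), seed=600 + rep
                )
                G = simulate_genotypes(spec)
                A = grm(G)
                rng = np.random.default_rng(900 + rep)
                L = np.linalg.cholesky(A + 1e-8 * np.eye(300))
                liab = L @ rng.standard_normal(300) * np.sqrt(h2) + rng.standard_normal(
                    300
                ) * np.sqrt(1 - h2)
                y = (liab > np.quantile(liab, 0.6)).astype(float)
                tr, te = np.arange(200), np.arange(200, 300)
                ks = KernelSet([A])
                vc = reml_fit(y[tr], None, KernelSet([A[:200, :200]]))
                pred = multiblup_predict(vc, ks, y[tr], None, tr, te)
                if len(np.unique(y[te])) == 2:
                    aucs[h2].append(auc(pred, y[te]))
        assert np.mean(aucs[0.6]) > np.mean(aucs[0.1])
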