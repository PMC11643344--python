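"""OLS GWAS, the spectral mixed model, and inflation diagnostics."""

import numpy as np
import pytest
from scipy import stats

from gwaskit.lmm import (
    CHI2_MEDIAN_1DF,
    fit_lmm_null,
    genomic_inflation,
    gwas_linreg,
    gwas_lmm,
)
from gwaskit.qc import mean_impute
from gwaskit.relatedness import compute_kinship
from gwaskit.synthetic import simulate_genotypes, simulate_phenotype


class TestLinreg:
    def test_perfect_fit(self):
        g = np.array([[0, 1, 2, 0, 1]], dtype=float).T
        y = np.array([1, 2, 3, 1, 2], dtype=float)
        res = gwas_linreg(g, y)
        assert res.table.loc[0, "beta"] == pytest.approx(1.0)
        assert res.table.loc[0, "p_value"] < 1e-10

    def test_orthogonal_trait(self):
        g = np.array([[0, 1, 0, 1]], dtype=float).T
        y = np.array([1, 1, -1, -1], dtype=float)
        assert gwas_linreg(g, y).table.loc[0, "beta"] == pytest.approx(0.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(50)
        G = rng.binomial(2, 0.3, size=(50, 20)).astype(float)
        y = rng.standard_normal(50)
        res = gwas_linreg(G, y).table
        n = 50
        for j in range(20):
            X = np.column_stack([np.ones(n), G[:, j]])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ coef
            s2 = (r @ r) / (n - 2)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            p = 2 * stats.t.sf(abs(coef[1] / se), n - 2)
            assert res.loc[j, "beta"] == pytest.approx(coef[1], abs=1e-10)
            assert res.loc[j, "se"] == pytest.approx(se, abs=1e-10)
            assert res.loc[j, "p_value"] == pytest.approx(p, abs=1e-10)

    def test_zero_variance_snp_sentinel(self):
        G = np.column_stack([np.ones(10), np.arange(10)]).astype(float)
        y = np.random.default_rng(0).standard_normal(10)
        res = gwas_linreg(G, y).table
        assert res.loc[0, "beta"] == 0.0 and res.loc[0, "p_value"] == 1.0

    def test_constant_trait_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gwas_linreg(np.eye(5), np.ones(5))


class TestNullFit:
    def test_noiseless_trait_shrinks_total_variance(self):
        rng = np.random.default_rng(1)
        n = 40
        K = compute_kinship(rng.binomial(2, 0.3, (n, 300)).astype(float))
        y = np.full(n, 3.14)  # y = X beta exactly, intercept-only design
        null = fit_lmm_null(y + 0.0, K)
        total = null.varcomp.sigma_g2 + null.varcomp.sigma_e2
        assert total <= 1e-8

    def test_identity_kinship_matches_ols_reml(self):
        rng = np.random.default_rng(2)
        n = 60
        y = rng.standard_normal(n) * 2 + 1
        null = fit_lmm_null(y, np.eye(n))
        ols_reml = y.var(ddof=1)  # intercept-only REML residual variance
        total = null.varcomp.sigma_g2 + null.varcomp.sigma_e2
        assert total == pytest.approx(ols_reml, abs=1e-6)

    def test_h2_consistency_invariant(self):
        rng = np.random.default_rng(3)
        g, _, _, _ = simulate_genotypes(150, 500, seed=3)
        pheno, _ = simulate_phenotype(g, n_causal=20, h2=0.5, seed=3)
        K = compute_kinship(mean_impute(g))
        vc = fit_lmm_null(pheno["value"].to_numpy(), K).varcomp
        assert vc.h2 == pytest.approx(1 / (1 + vc.delta), abs=1e-8)
        assert vc.sigma_g2 >= 0 and vc.sigma_e2 >= 0

    def test_rank_deficient_design_rejected(self):
        n = 20
        X = np.ones((n, 2))
        with pytest.raises(ValueError, match="rank"):
            fit_lmm_null(np.random.default_rng(0).standard_normal(n), np.eye(n), X=X)


class TestLMMScan:
    def test_identity_kinship_equals_ols(self):
        """With K=I and delta fixed, mixed-model betas equal OLS betas and
        p-values agree once the OLS t reference is swapped for the normal
        (chi-square 1df) reference used by the Wald test."""
        rng = np.random.default_rng(4)
        G = rng.binomial(2, 0.4, size=(80, 40)).astype(float)
        y = rng.standard_normal(80)
        lmm = gwas_lmm(G, y, np.eye(80)).table
        ols = gwas_linreg(G, y).table
        assert lmm["beta"].to_numpy() == pytest.approx(ols["beta"].to_numpy(), abs=1e-8)
        z = ols["beta"] / ols["se"]
        p_norm = stats.chi2.sf(z**2, 1)
        assert lmm["p_value"].to_numpy() == pytest.approx(p_norm, abs=1e-6)

    def test_intercept_absorption(self):
        rng = np.random.default_rng(5)
        g, _, _, _ = simulate_genotypes(100, 200, seed=5)
        imputed = mean_impute(g)
        K = compute_kinship(imputed)
        y = rng.standard_normal(100)
        a = gwas_lmm(imputed, y, K).table["p_value"].to_numpy()
        b = gwas_lmm(imputed, y + 17.0, K).table["p_value"].to_numpy()
        assert a == pytest.approx(b, rel=1e-6)

    def test_refit_never_worse_loglik(self):
        rng = np.random.default_rng(6)
        g, _, _, _ = simulate_genotypes(60, 25, seed=6)
        imputed = mean_impute(g)
        K = compute_kinship(imputed)
        pheno, _ = simulate_phenotype(g, n_causal=3, h2=0.5, seed=6)
        y = pheno["value"].to_numpy()
        null = fit_lmm_null(y, K)
        fixed = gwas_lmm(imputed, y, K, null=null).table["loglik"].to_numpy()
        refit = gwas_lmm(imputed, y, K, null=null, refit_delta_per_snp=True).table[
            "loglik"
        ].to_numpy()
        assert (refit >= fixed - 1e-8).all()

    def test_single_causal_snp_is_top_hit(self):
        hits = 0
        for seed in range(5):
            g, v, _, _ = simulate_genotypes(200, 400, seed=60 + seed)
            pheno, truth = simulate_phenotype(g, n_causal=1, h2=0.2, seed=60 + seed)
            imputed = mean_impute(g)
            K = compute_kinship(imputed)
            res = gwas_lmm(imputed, pheno["value"].to_numpy(), K, v)
            if int(res.table["p_value"].idxmin()) == truth.causal_indices[0]:
                hits += 1
        assert hits >= 4

    def test_null_pvalues_uniform(self):
        """Fully null unstructured trait: mixed-model p-values are uniform
        (KS statistic < 0.02 at 10^4 SNPs)."""
        g, _, _, _ = simulate_genotypes(150, 10_000, seed=7)
        imputed = mean_impute(g)
        K = compute_kinship(imputed)
        y = np.random.default_rng(7).standard_normal(150)
        p = gwas_lmm(imputed, y, K).table["p_value"].to_numpy()
        ks = stats.kstest(p, "uniform").statistic
        assert ks < 0.02


class TestInflation:
    def test_all_half(self):
        assert genomic_inflation(np.full(100, 0.5)) == pytest.approx(1.0)

    def test_uniform_null(self):
        p = np.random.default_rng(8).uniform(size=100_000)
        p = np.clip(p, 1e-12, 1.0)
        assert 0.98 <= genomic_inflation(p) <= 1.02

    def test_monotone_in_signal(self):
        p = np.random.default_rng(9).uniform(0.01, 1.0, size=5000)
        assert genomic_inflation(p / 2) > genomic_inflation(p)

    def test_median_constant_documented(self):
        assert CHI2_MEDIAN_1DF == pytest.approx(0.4549364, abs=1e-7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation([])
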