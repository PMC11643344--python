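"""Repeated-split importance GWAS, genomic prediction, and the
agreement statistics."""

import numpy as np
import pytest

from gwaskit.ml import (
    MLConfig,
    bland_altman,
    gblup_predict,
    gp_holdout,
    ml_gwas,
    pearson_correlation,
    ridge_gwas_scores,
)
from gwaskit.qc import mean_impute
from gwaskit.relatedness import compute_kinship
from gwaskit.synthetic import simulate_genotypes, simulate_phenotype


@pytest.fixture(scope="module")
def sim200():
    g, _, _, _ = simulate_genotypes(200, 150, seed=40)
    return mean_impute(g)


class TestConfig:
    def test_protocol_defaults(self):
        cfg = MLConfig()
        assert (cfg.n_iterations, cfg.train_fraction, cfg.n_trees, cfg.max_depth) == (
            10,
            0.7,
            200,
            3,
        )
        assert cfg.aggregate == "sum"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"learner": "svm"},
            {"n_iterations": 0},
            {"train_fraction": 1.0},
            {"aggregate": "max"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MLConfig(**kwargs)


class TestMLGwas:
    @pytest.mark.parametrize("learner", ["random_forest", "gradient_boosted_trees", "ridge"])
    def test_constant_trait_zero_importance(self, sim200, learner):
        cfg = MLConfig(learner=learner, n_iterations=2, n_trees=10, seed=1)
        res = ml_gwas(sim200, np.full(200, 2.0), cfg)
        assert np.allclose(res.scores, 0.0)

    def test_mean_is_sum_over_iterations(self, sim200):
        y = np.random.default_rng(41).standard_normal(200)
        a = ml_gwas(sim200, y, MLConfig(learner="ridge", n_iterations=4, seed=2, aggregate="sum"))
        b = ml_gwas(sim200, y, MLConfig(learner="ridge", n_iterations=4, seed=2, aggregate="mean"))
        assert b.scores == pytest.approx(a.scores / 4)

    def test_bitwise_reproducible(self, sim200):
        y = np.random.default_rng(42).standard_normal(200)
        cfg = MLConfig(learner="random_forest", n_iterations=2, n_trees=20, seed=3)
        a = ml_gwas(sim200, y, cfg)
        b = ml_gwas(sim200, y, cfg)
        assert np.array_equal(a.scores, b.scores)
        assert np.array_equal(a.test_r2, b.test_r2)

    def test_tree_importances_normalized_per_iteration(self, sim200):
        g, _, _, _ = simulate_genotypes(100, 80, seed=43)
        pheno, _ = simulate_phenotype(g, n_causal=5, h2=0.8, seed=43)
        cfg = MLConfig(learner="random_forest", n_iterations=3, n_trees=25, seed=4)
        res = ml_gwas(mean_impute(g), pheno["value"].to_numpy(), cfg)
        assert (res.per_iteration >= 0).all()
        sums = res.per_iteration.sum(axis=1)
        assert ((sums <= 1 + 1e-8) | (sums == 0)).all()

    def test_causal_snp_found_by_trees(self):
        hits = {"random_forest": 0, "gradient_boosted_trees": 0}
        for seed in range(3):
            g, _, _, _ = simulate_genotypes(150, 200, seed=70 + seed)
            pheno, truth = simulate_phenotype(g, n_causal=1, h2=0.3, seed=70 + seed)
            X = mean_impute(g)
            y = pheno["value"].to_numpy()
            for learner in hits:
                cfg = MLConfig(learner=learner, n_iterations=3, n_trees=50, seed=seed)
                res = ml_gwas(X, y, cfg)
                if int(np.argmax(res.scores)) == truth.causal_indices[0]:
                    hits[learner] += 1
        assert all(h >= 2 for h in hits.values())


class TestRidgeScores:
    def test_linear_signal_ranks_first(self):
        rng = np.random.default_rng(44)
        X = rng.binomial(2, 0.3, size=(150, 50)).astype(float)
        y = 2.0 * (X[:, 7] - X[:, 7].mean()) / X[:, 7].std()
        res = ridge_gwas_scores(X, y, MLConfig(n_iterations=3, seed=5))
        assert int(np.argmax(res.scores)) == 7

    def test_duplicated_column_symmetry(self):
        rng = np.random.default_rng(45)
        X = rng.binomial(2, 0.3, size=(120, 30)).astype(float)
        X[:, 12] = X[:, 3]
        pheno = rng.standard_normal(120) + X[:, 3]
        res = ridge_gwas_scores(X, pheno, MLConfig(n_iterations=2, seed=6))
        assert res.scores[3] == pytest.approx(res.scores[12], abs=1e-8)

    def test_zero_trait_zero_scores(self):
        rng = np.random.default_rng(46)
        X = rng.binomial(2, 0.3, size=(50, 20)).astype(float)
        res = ridge_gwas_scores(X, np.zeros(50), MLConfig(n_iterations=2, seed=7))
        assert np.allclose(res.scores, 0.0)


class TestAgreementStats:
    def test_pearson_exact_cases(self):
        assert pearson_correlation([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        a = np.array([0.3, -1.2, 2.0, 0.7])
        assert pearson_correlation(a, -a) == pytest.approx(-1.0)

    def test_pearson_matches_formula(self):
        rng = np.random.default_rng(47)
        a, b = rng.standard_normal(100), rng.standard_normal(100)
        expected = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
            ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
        )
        assert pearson_correlation(a, b) == pytest.approx(expected, abs=1e-12)

    def test_pearson_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_bland_altman_cases(self):
        obs = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(obs, obs)
        assert (ba.bias, ba.loa_low, ba.loa_high) == (0.0, 0.0, 0.0)
        ba = bland_altman(obs + 1, obs)
        assert ba.bias == pytest.approx(1.0) and ba.sd_diff == pytest.approx(0.0)
        ba = bland_altman(np.array([1.0, -1.0]), np.zeros(2))
        assert ba.sd_diff == pytest.approx(np.sqrt(2))
        assert ba.loa_high == pytest.approx(1.96 * np.sqrt(2))


class TestGBLUP:
    def test_pure_noise_shrinks_to_mean(self):
        rng = np.random.default_rng(48)
        X = rng.binomial(2, 0.3, size=(120, 300)).astype(float)
        y = rng.standard_normal(120)  # no genetic signal
        K = compute_kinship(X)
        train = np.arange(90)
        test = np.arange(90, 120)
        pred = gblup_predict(K, y[:90], train, test)
        mu = y[:90].mean()
        assert np.abs(pred - mu).max() < 0.5 * y[:90].std()

    def test_duplicate_sample_recovers_trait(self):
        g, _, _, _ = simulate_genotypes(100, 500, seed=49)
        pheno, _ = simulate_phenotype(g, n_causal=20, h2=1.0, seed=49)
        X = mean_impute(g)
        X[99] = X[0]  # test sample genetically identical to a training one
        y = pheno["value"].to_numpy()
        y[99] = y[0]
        K = compute_kinship(X)
        pred = gblup_predict(K, y[:99], np.arange(99), np.array([99]))
        assert abs(pred[0] - y[0]) < 0.1 * y.std()

    def test_disjoint_index_check(self):
        K = compute_kinship(np.random.default_rng(0).random((10, 20)))
        with pytest.raises(ValueError, match="disjoint"):
            gblup_predict(K, np.zeros(5), np.arange(5), np.arange(4, 8))


class TestHoldout:
    def test_single_model_equals_direct_run(self, sim200):
        y = np.random.default_rng(50).standard_normal(200)
        cfg = MLConfig(n_trees=20, seed=8)
        a = gp_holdout(sim200, y, "random_forest", n_holdout=30, n_models=1, cfg=cfg, seed=8)
        b = gp_holdout(sim200, y, "random_forest", n_holdout=30, n_models=1, cfg=cfg, seed=8)
        assert np.array_equal(a.predicted, b.predicted)
        assert np.array_equal(a.holdout_indices, b.holdout_indices)

    def test_gblup_collapses_model_count(self, sim200):
        pheno = np.random.default_rng(51).standard_normal(200)
        res = gp_holdout(sim200, pheno, "gblup", n_holdout=20, n_models=10, seed=9)
        assert res.n_models == 1 and any("deterministic" in n for n in res.notes)

    def test_strong_signal_ridge(self):
        """Noiseless additive trait with fewer markers than training
        samples: ridge prediction is near-perfect.  (With markers far
        outnumbering samples the min-norm ridge solution cannot exploit
        a sparse architecture and the correlation plateaus well below 1,
        so the check lives in the identifiable regime.)"""
        g, _, _, _ = simulate_genotypes(300, 150, seed=52)
        pheno, _ = simulate_phenotype(g, n_causal=5, h2=1.0, seed=52)
        res = gp_holdout(
            mean_impute(g), pheno["value"].to_numpy(), "ridge",
            n_holdout=60, n_models=1, seed=10,
        )
        assert res.pearson_r > 0.9

    def test_constant_observed_reports_ba_without_r(self, sim200):
        y = np.zeros(200)
        y[:50] = 0.0
        res = gp_holdout(sim200, y + 1.0, "ridge", n_holdout=20, n_models=1, seed=11)
        assert np.isnan(res.pearson_r)
        assert np.isfinite(res.bland_altman.bias)
        assert any("undefined" in n for n in res.notes)
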