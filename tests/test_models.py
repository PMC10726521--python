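import numpy as np
import pandas as pd
import pytest

from gsel import (
    BRRPriors,
    MLModelSpec,
    SimConfig,
    fit_brr,
    fit_gblup,
    fit_ml,
    fit_rrblup,
    simulate_genotypes,
    simulate_trait,
    vanraden_g,
)
from gsel.kinship import KinshipMatrix


@pytest.fixture(scope="module")
def ridge_panel():
    geno, _ = simulate_genotypes(
        SimConfig(n_individuals=60, n_chromosomes=2, markers_per_chromosome=100,
                  chromosome_length_bp=1_000_000, seed=41))
    truth = simulate_trait(geno, 30, 0.5, seed=42)
    y = pd.Series(truth.phenotype, index=geno.individual_ids)
    return geno, y


class TestRRBLUP:
    def test_effects_match_dense_ridge_solve(self, ridge_panel):
        """Marker effects equal the brute-force solve of (W'W + lambda I) a = W'(y - mu)."""
        geno, y = ridge_panel
        fit = fit_rrblup(geno, y)
        lam = fit.diagnostics["lambda"]
        W = geno.dosages - geno.dosages.mean(axis=0)
        a_dense = np.linalg.solve(W.T @ W + lam * np.eye(W.shape[1]),
                                  W.T @ (y.to_numpy() - fit.mu))
        assert np.abs(fit.marker_effects - a_dense).max() < 1e-8

    def test_gebvs_are_mu_plus_w_effects(self, ridge_panel):
        geno, y = ridge_panel
        fit = fit_rrblup(geno, y)
        W = geno.dosages - geno.dosages.mean(axis=0)
        np.testing.assert_allclose(fit.gebvs.to_numpy(), fit.mu + W @ fit.marker_effects,
                                   atol=1e-10)

    def test_constant_phenotype_gives_flat_gebvs(self, ridge_panel):
        geno, _ = ridge_panel
        y = pd.Series(3.0, index=geno.individual_ids)
        fit = fit_rrblup(geno, y)
        assert fit.variance.sigma2_a == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(fit.gebvs.to_numpy(), 3.0, atol=1e-10)

    def test_phenotype_shift_moves_mu_only(self, ridge_panel):
        geno, y = ridge_panel
        a = fit_rrblup(geno, y)
        b = fit_rrblup(geno, y + 10.0)
        assert b.mu == pytest.approx(a.mu + 10.0, abs=1e-6)
        np.testing.assert_allclose(b.gebvs - b.mu, a.gebvs - a.mu, atol=1e-6)

    def test_too_few_records_rejected(self, ridge_panel):
        geno, y = ridge_panel
        small = geno.subset(individual_ids=geno.individual_ids[:5])
        with pytest.raises(ValueError, match="10 training records"):
            fit_rrblup(small, y.iloc[:5])


class TestGBLUP:
    def test_equivalence_with_rrblup(self, ridge_panel):
        geno, y = ridge_panel
        fr = fit_rrblup(geno, y)
        fg = fit_gblup(vanraden_g(geno), y)
        assert np.abs(fr.gebvs - fg.gebvs).max() < 1e-6

    def test_identity_kinship_transfers_no_information(self, ridge_panel):
        """K = I: held-out individuals have no relatives, so their GEBV is mu."""
        geno, y = ridge_panel
        ids = geno.individual_ids
        K = KinshipMatrix(ids, np.eye(len(ids)))
        fit = fit_gblup(K, y.iloc[:50], predict_ids=ids[50:])
        np.testing.assert_allclose(fit.gebvs.loc[ids[50:]].to_numpy(), fit.mu, atol=1e-8)

    def test_duplicated_individual_predicts_like_its_twin(self, ridge_panel):
        geno, y = ridge_panel
        ids = geno.individual_ids
        dup = geno.subset(individual_ids=ids[:1])
        dup.individual_ids = ["twin"]
        merged_dos = np.vstack([geno.dosages, dup.dosages])
        from gsel import GenotypeMatrix

        merged = GenotypeMatrix(ids + ["twin"], geno.marker_ids, merged_dos)
        K = vanraden_g(merged)
        fit = fit_gblup(K, y, predict_ids=["twin"])
        assert fit.gebvs.loc["twin"] == pytest.approx(fit.gebvs.loc[ids[0]], abs=1e-8)

    def test_held_out_prediction_matches_rrblup(self, ridge_panel):
        geno, y = ridge_panel
        ids = geno.individual_ids
        train, test = ids[:45], ids[45:]
        geno_tr = geno.subset(individual_ids=train)
        fr = fit_rrblup(geno_tr, y.loc[train])
        # Kinship from the same centered dosages as the RRBLUP training fit
        center = geno_tr.dosages.mean(axis=0)
        p = center / 2.0
        poly = (p > 0) & (p < 1)
        denom = 2.0 * np.sum(p[poly] * (1 - p[poly]))
        W_all = geno.dosages[:, poly] - center[poly]
        K = KinshipMatrix(ids, W_all @ W_all.T / denom)
        fg = fit_gblup(K, y.loc[train], predict_ids=test)
        pr = fr.predict(geno.subset(individual_ids=test))
        np.testing.assert_allclose(fg.gebvs.loc[test].to_numpy(), pr.to_numpy(), atol=1e-6)


class TestBRR:
    def test_fixed_variance_posterior_matches_ridge(self, ridge_panel):
        """With variances frozen at REML values the posterior mean is the ridge solution."""
        geno, y = ridge_panel
        fr = fit_rrblup(geno, y)
        fb = fit_brr(geno, y, BRRPriors(n_iter=3000, burn_in=300), seed=1,
                     fixed_variances=(fr.variance.sigma2_a, fr.variance.sigma2_e),
                     store_effect_samples=True)
        samples = fb.diagnostics["effect_samples"]
        nb = 30
        bs = samples.shape[0] // nb
        batch_means = samples[: nb * bs].reshape(nb, bs, -1).mean(axis=1)
        se = batch_means.std(axis=0, ddof=1) / np.sqrt(nb)
        diff = np.abs(fb.marker_effects - fr.marker_effects)
        assert np.linalg.norm(diff) <= 3.0 * np.linalg.norm(se)

    def test_seed_reproducibility(self, ridge_panel):
        geno, y = ridge_panel
        priors = BRRPriors(n_iter=200, burn_in=20)
        a = fit_brr(geno, y, priors, seed=7)
        b = fit_brr(geno, y, priors, seed=7)
        np.testing.assert_array_equal(a.marker_effects, b.marker_effects)
        np.testing.assert_array_equal(a.gebvs.to_numpy(), b.gebvs.to_numpy())

    def test_zero_variance_phenotype_centers_effects_at_zero(self, ridge_panel):
        geno, _ = ridge_panel
        y = pd.Series(1.0, index=geno.individual_ids)
        fit = fit_brr(geno, y, BRRPriors(n_iter=400, burn_in=100), seed=2)
        assert np.abs(fit.marker_effects).max() < 0.05
        assert fit.mu == pytest.approx(1.0, abs=0.05)

    def test_posterior_shrinks_relative_to_ols(self):
        """On a well-conditioned m < n toy the Gaussian prior shrinks each effect."""
        rng = np.random.default_rng(3)
        n, m = 200, 8
        from gsel import GenotypeMatrix

        dosages = rng.integers(0, 3, size=(n, m)).astype(float)
        beta = rng.standard_normal(m)
        y_arr = dosages @ beta + rng.standard_normal(n) * 2.0
        geno = GenotypeMatrix([f"s{i}" for i in range(n)], [f"m{j}" for j in range(m)], dosages)
        y = pd.Series(y_arr, index=geno.individual_ids)
        W = dosages - dosages.mean(axis=0)
        ols = np.linalg.lstsq(np.column_stack([np.ones(n), W]), y_arr, rcond=None)[0][1:]
        fit = fit_brr(geno, y, BRRPriors(n_iter=2000, burn_in=200), seed=4)
        assert np.all(np.abs(fit.marker_effects) <= np.abs(ols) + 0.02)


class TestML:
    def test_rf_deterministic_under_seed(self, ridge_panel):
        geno, y = ridge_panel
        spec = MLModelSpec(family="rf", grid={"n_estimators": [50], "max_features": ["sqrt"],
                                              "max_depth": [20]})
        a = fit_ml(geno, y, spec, seed=5)
        b = fit_ml(geno, y, spec, seed=5)
        np.testing.assert_array_equal(a.gebvs.to_numpy(), b.gebvs.to_numpy())

    def test_more_trees_do_not_hurt_on_noiseless_trait(self):
        geno, _ = simulate_genotypes(
            SimConfig(n_individuals=150, n_chromosomes=2, markers_per_chromosome=60, seed=51))
        truth = simulate_trait(geno, 20, 1.0, seed=52)
        y = pd.Series(truth.phenotype, index=geno.individual_ids)
        train = geno.subset(individual_ids=geno.individual_ids[:100])
        test = geno.subset(individual_ids=geno.individual_ids[100:])
        y_te = truth.phenotype[100:]
        mses = {}
        for n_trees in (1, 500):
            spec = MLModelSpec(family="rf", grid={"n_estimators": [n_trees],
                                                  "max_features": ["auto"], "max_depth": [40]})
            fit = fit_ml(train, y.iloc[:100], spec, seed=6, predict_geno=test)
            mses[n_trees] = np.mean((fit.gebvs.loc[test.individual_ids].to_numpy() - y_te) ** 2)
        assert mses[500] <= mses[1]

    def test_constant_phenotype_predicts_constant(self, ridge_panel):
        geno, _ = ridge_panel
        y = pd.Series(2.5, index=geno.individual_ids)
        spec = MLModelSpec(family="rf", grid={"n_estimators": [20], "max_features": ["sqrt"],
                                              "max_depth": [10]})
        fit = fit_ml(geno, y, spec, seed=7)
        np.testing.assert_allclose(fit.gebvs.to_numpy(), 2.5, atol=1e-12)

    def test_chosen_hyperparameters_come_from_grid(self, ridge_panel):
        geno, y = ridge_panel
        grid = {"n_estimators": [10, 30], "max_features": ["sqrt"], "max_depth": [10]}
        fit = fit_ml(geno, y, MLModelSpec(family="rf", grid=grid), seed=8)
        assert fit.hyperparameters["n_estimators"] in grid["n_estimators"]
        assert fit.model == "rf"

    def test_cnn_runs_and_is_deterministic(self, ridge_panel):
        geno, y = ridge_panel
        spec = MLModelSpec(family="cnn", grid={"n_filters": [8], "dropout": [0.2]})
        a = fit_ml(geno, y, spec, seed=9)
        b = fit_ml(geno, y, spec, seed=9)
        np.testing.assert_array_equal(a.gebvs.to_numpy(), b.gebvs.to_numpy())
        assert np.std(a.gebvs.to_numpy()) > 0

    def test_mlp_grid_search_smoke(self, ridge_panel):
        geno, y = ridge_panel
        spec = MLModelSpec(family="mlp", grid={"hidden_layers": [1], "neurons": [10],
                                               "activation": ["relu"], "solver": ["lbfgs"],
                                               "learning_rate": ["constant"], "alpha": [0.001]})
        fit = fit_ml(geno, y, spec, seed=10)
        assert len(fit.gebvs) == geno.n_individuals
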