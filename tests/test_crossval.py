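import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gsel import (
    CVResult,
    SimConfig,
    compare_marker_sets,
    cv_accuracy,
    gebv_report,
    make_folds,
    rank_correlation,
    simulate_genotypes,
    simulate_trait,
)
from gsel.crossval import _fit_and_predict


class TestMakeFolds:
    def test_fold_sizes_for_204_individuals(self):
        folds = make_folds(204, k=10, seed=0)
        sizes = sorted(np.bincount(folds, minlength=10))
        assert sizes == [20] * 6 + [21] * 4

    def test_leave_one_out_when_k_equals_n(self):
        folds = make_folds(8, k=8, seed=1)
        assert sorted(folds) == list(range(8))

    def test_seed_reproducibility(self):
        np.testing.assert_array_equal(make_folds(57, 10, seed=3), make_folds(57, 10, seed=3))

    def test_exact_partition(self):
        folds = make_folds(101, k=10, seed=4)
        assert len(folds) == 101 and set(folds) == set(range(10))


@pytest.fixture(scope="module")
def cv_panel():
    geno, _ = simulate_genotypes(
        SimConfig(n_individuals=100, n_chromosomes=2, markers_per_chromosome=150,
                  chromosome_length_bp=1_500_000, seed=71))
    return geno


class TestCVAccuracy:
    def test_training_mean_model_scores_zero_on_null(self, cv_panel):
        """A memorising model returning the training mean has no within-fold
        signal: per-fold accuracy is exactly the recorded-as-zero convention."""
        rng = np.random.default_rng(72)
        y = pd.Series(rng.standard_normal(100), index=cv_panel.individual_ids)

        def mean_model(geno_tr, y_tr, geno_te):
            return np.full(geno_te.n_individuals, float(y_tr.mean()))

        with pytest.warns(UserWarning, match="constant"):
            result = cv_accuracy(mean_model, cv_panel, y, k=5, n_iterations=5, seed=0,
                                 accuracy_mode="per_fold")
        assert abs(result.mean) < 1e-9

    def test_true_bv_oracle_bounds_fitted_models(self, cv_panel):
        truth = simulate_trait(cv_panel, 40, 0.8, seed=73)
        y = pd.Series(truth.phenotype, index=cv_panel.individual_ids)
        bv = pd.Series(truth.true_breeding_values, index=cv_panel.individual_ids)

        def oracle(geno_tr, y_tr, geno_te):
            return bv.loc[geno_te.individual_ids].to_numpy()

        acc_oracle = cv_accuracy(oracle, cv_panel, y, k=5, n_iterations=2, seed=1).mean
        acc_rrblup = cv_accuracy("rrblup", cv_panel, y, k=5, n_iterations=2, seed=1).mean
        assert acc_oracle > 0.8
        assert acc_rrblup <= acc_oracle + 0.05

    def test_permuted_phenotypes_score_near_zero(self, cv_panel):
        truth = simulate_trait(cv_panel, 40, 0.8, seed=74)
        rng = np.random.default_rng(75)
        y = pd.Series(rng.permutation(truth.phenotype), index=cv_panel.individual_ids)
        result = cv_accuracy("rrblup", cv_panel, y, k=5, n_iterations=5, seed=2)
        assert abs(result.mean) < 0.25

    def test_no_leakage_from_test_fold_phenotypes(self, cv_panel):
        """Corrupting held-out phenotypes leaves their predictions unchanged."""
        truth = simulate_trait(cv_panel, 40, 0.6, seed=76)
        y = pd.Series(truth.phenotype, index=cv_panel.individual_ids)
        ids = np.array(cv_panel.individual_ids)
        folds = make_folds(100, k=5, seed=3)
        test_ids = list(ids[folds == 0])
        train_ids = list(ids[folds != 0])
        before = _fit_and_predict("rrblup", cv_panel, y, train_ids, test_ids, seed=0,
                                  model_kwargs={})
        corrupted = y.copy()
        corrupted.loc[test_ids] = 999.0
        after = _fit_and_predict("rrblup", cv_panel, corrupted, train_ids, test_ids, seed=0,
                                 model_kwargs={})
        np.testing.assert_array_equal(before, after)

    def test_gblup_and_rrblup_agree_under_cv(self, cv_panel):
        truth = simulate_trait(cv_panel, 40, 0.6, seed=77)
        y = pd.Series(truth.phenotype, index=cv_panel.individual_ids)
        a = cv_accuracy("rrblup", cv_panel, y, k=5, n_iterations=2, seed=4)
        b = cv_accuracy("gblup", cv_panel, y, k=5, n_iterations=2, seed=4)
        # GBLUP's kinship centering uses the full panel; agreement is close, not exact
        np.testing.assert_allclose(a.accuracies, b.accuracies, atol=0.02)

    def test_constant_prediction_recorded_as_zero(self, cv_panel):
        y = pd.Series(np.arange(100, dtype=float), index=cv_panel.individual_ids)

        def constant_model(geno_tr, y_tr, geno_te):
            return np.zeros(geno_te.n_individuals)

        with pytest.warns(UserWarning, match="constant"):
            result = cv_accuracy(constant_model, cv_panel, y, k=5, n_iterations=1, seed=5)
        assert result.accuracies[0] == 0.0


class TestCompareMarkerSets:
    def _cv(self, accs):
        return CVResult("t", "m", "whole", np.asarray(accs, dtype=float), seed=0)

    def test_identical_results_give_t_zero_p_one(self):
        a = self._cv([0.3, 0.31, 0.29])
        assert compare_marker_sets(a, self._cv([0.3, 0.31, 0.29])) == (0.0, 1.0)

    def test_degenerate_zero_variance_convention(self):
        t, p = compare_marker_sets(self._cv([0.3] * 10), self._cv([0.2] * 10))
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_matches_textbook_pooled_t(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0.30, 0.02, 10)
        y = rng.normal(0.32, 0.02, 10)
        t, p = compare_marker_sets(self._cv(x), self._cv(y))
        # independent oracle: textbook pooled-variance formula
        sp2 = (9 * x.var(ddof=1) + 9 * y.var(ddof=1)) / 18
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 10 + 1 / 10))
        p_hand = 2 * stats.t.sf(abs(t_hand), 18)
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert p == pytest.approx(p_hand, abs=1e-12)


class TestRankCorrelation:
    def test_monotone_gives_one(self):
        x = np.arange(8.0)
        rho, _ = rank_correlation(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self):
        x = np.arange(8.0)
        rho, _ = rank_correlation(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_midrank_ties_handled(self):
        rho, _ = rank_correlation([1.0, 1.0, 2.0, 3.0], [10.0, 20.0, 30.0, 40.0])
        expected, _ = stats.spearmanr([1, 1, 2, 3], [10, 20, 30, 40])
        assert rho == pytest.approx(expected)


class TestGEBVReport:
    def test_summary_matches_hand_arithmetic(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        report = gebv_report(pd.DataFrame({"t": values}))
        row = report["summary"].iloc[0]
        assert row["mean"] == pytest.approx(5.5)
        assert row["sd"] == pytest.approx(np.std(values, ddof=1))
        assert row["se_mean"] == pytest.approx(np.std(values, ddof=1) / np.sqrt(10))
        assert (row["min"], row["max"]) == (1.0, 10.0)

    def test_identical_traits_correlate_perfectly(self):
        v = np.array([0.1, 0.5, 0.9, 0.2, 0.7])
        report = gebv_report(pd.DataFrame({"a": v, "b": v}))
        assert report["correlations"].iloc[0]["r"] == pytest.approx(1.0)

    def test_constant_gebvs_reported_as_na(self):
        report = gebv_report(pd.DataFrame({"a": np.ones(5), "b": np.arange(5.0)}))
        assert report["summary"].set_index("trait").loc["a", "sd"] == 0.0
        assert np.isnan(report["correlations"].iloc[0]["r"])
        assert np.isnan(report["summary"].set_index("trait").loc["a", "shapiro_p"])
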