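import numpy as np
import pandas as pd
import pytest

from gsel import SimConfig, simulate_environment_trials, simulate_genotypes, simulate_trait
from gsel.synthetic import ConfigError, inject_missing


def _adjacent_r(dosages):
    X = dosages - dosages.mean(axis=0)
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    X = X / norms
    return np.einsum("ij,ij->j", X[:, :-1], X[:, 1:])


class TestSimulateGenotypes:
    def test_deterministic_under_seed(self):
        cfg = SimConfig(n_individuals=50, n_chromosomes=2, markers_per_chromosome=80, seed=5)
        a, amap = simulate_genotypes(cfg)
        b, bmap = simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        np.testing.assert_array_equal(amap.positions_bp, bmap.positions_bp)

    def test_no_ld_when_rho_zero(self):
        cfg = SimConfig(n_individuals=400, n_chromosomes=4, markers_per_chromosome=500,
                        ld_decay_rho=0.0, seed=1)
        geno, _ = simulate_genotypes(cfg)
        r = _adjacent_r(geno.dosages)
        assert np.mean(np.abs(r)) < 0.05

    def test_high_rho_gives_decaying_ld(self):
        cfg = SimConfig(n_individuals=300, n_chromosomes=2, markers_per_chromosome=400,
                        ld_decay_rho=0.95, seed=2)
        geno, _ = simulate_genotypes(cfg)
        X = geno.dosages - geno.dosages.mean(axis=0)
        norms = np.linalg.norm(X, axis=0)
        norms[norms == 0] = 1.0
        X = X / norms
        adj = np.mean([(X[:, j] @ X[:, j + 1]) ** 2 for j in range(399)])
        far = np.mean([(X[:, j] @ X[:, j + 50]) ** 2 for j in range(300)])
        assert adj > far

    def test_ld_monotone_in_distance_class(self):
        cfg = SimConfig(n_individuals=300, n_chromosomes=2, markers_per_chromosome=300,
                        ld_decay_rho=0.9, seed=3)
        geno, _ = simulate_genotypes(cfg)
        X = geno.dosages[:, :300]
        X = X - X.mean(axis=0)
        norms = np.linalg.norm(X, axis=0)
        norms[norms == 0] = 1.0
        X = X / norms
        means = []
        for lag in (1, 5, 20, 80):
            means.append(np.mean([(X[:, j] @ X[:, j + lag]) ** 2 for j in range(300 - lag)]))
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_maf_spectrum_within_range(self):
        cfg = SimConfig(n_individuals=500, n_chromosomes=2, markers_per_chromosome=400,
                        maf_range=(0.1, 0.4), ld_decay_rho=0.5, seed=4)
        geno, _ = simulate_genotypes(cfg)
        maf = geno.minor_allele_frequencies()
        # allow binomial sampling error around the drawn frequencies
        assert np.quantile(maf, 0.01) > 0.05 and maf.max() <= 0.5

    def test_positions_strictly_increasing(self):
        _, gmap = simulate_genotypes(SimConfig(n_individuals=10, seed=6))
        for chrom in set(gmap.chromosomes):
            pos = gmap.positions_bp[gmap.chromosomes == chrom]
            assert np.all(np.diff(pos) > 0)

    @pytest.mark.parametrize("kwargs", [
        {"ld_decay_rho": 1.0}, {"ld_decay_rho": -0.1},
        {"maf_range": (0.3, 0.2)}, {"maf_range": (0.0, 0.5)},
        {"n_individuals": 0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimConfig(**kwargs)


class TestSimulateTrait:
    def test_h2_one_is_noiseless(self, small_panel):
        geno, _ = small_panel
        truth = simulate_trait(geno, 40, 1.0, seed=9)
        np.testing.assert_array_equal(truth.phenotype, truth.true_breeding_values)

    def test_h2_zero_has_no_signal(self, small_panel):
        geno, _ = small_panel
        rs = [np.corrcoef(simulate_trait(geno, 40, 0.0, seed=s).phenotype,
                          simulate_trait(geno, 40, 0.0, seed=s).true_breeding_values)[0, 1]
              for s in range(30)]
        assert abs(np.mean(rs)) < 0.1

    def test_realized_h2_near_target(self):
        geno, _ = simulate_genotypes(SimConfig(n_individuals=500, n_chromosomes=4,
                                               markers_per_chromosome=500, seed=21))
        vals = []
        for s in range(20):
            truth = simulate_trait(geno, 50, 0.5, seed=100 + s)
            bv, ph = truth.true_breeding_values, truth.phenotype
            vals.append(np.var(bv) / np.var(ph))
        assert 0.45 < np.mean(vals) < 0.55

    def test_deterministic_and_qtl_subset(self, small_panel):
        geno, gmap = small_panel
        a = simulate_trait(geno, 30, 0.4, seed=7)
        b = simulate_trait(geno, 30, 0.4, seed=7)
        np.testing.assert_array_equal(a.phenotype, b.phenotype)
        assert set(a.qtl_marker_ids) <= set(gmap.marker_ids)

    def test_invalid_h2_rejected(self, small_panel):
        geno, _ = small_panel
        with pytest.raises(ConfigError):
            simulate_trait(geno, 10, 1.5, seed=0)


class TestEnvironmentTrials:
    def test_zero_noise_recovers_genotypic_value(self, small_panel, small_trait):
        geno, _ = small_panel
        truth = simulate_trait(geno, 40, 1.0, seed=3, gxe_ratio=0.0)
        trials, adjusted = simulate_environment_trials(
            truth, geno.individual_ids, n_env=2, n_rep=2, target_H2=1.0, seed=1)
        g = truth.true_breeding_values
        np.testing.assert_allclose(adjusted["value"].to_numpy(), g, atol=1e-10)
        per_env = trials.pivot_table(index="genotype_id", columns="environment", values="value")
        per_env = per_env.reindex(geno.individual_ids)
        np.testing.assert_allclose(per_env.to_numpy(), np.column_stack([g, g]), atol=1e-10)

    def test_realized_H2_matches_target(self, small_panel):
        geno, _ = small_panel
        truth = simulate_trait(geno, 40, 0.8, seed=4, gxe_ratio=0.3)
        ratios = []
        for s in range(25):
            trials, _ = simulate_environment_trials(
                truth, geno.individual_ids, n_env=3, n_rep=2, target_H2=0.6, seed=s)
            wide = trials.pivot_table(index="genotype_id", columns=["environment", "rep"],
                                      values="value").reindex(geno.individual_ids)
            means = wide.mean(axis=1).to_numpy()
            # Var(mean) = s2_G + s2_GE/n + s2_e/(nr); H2 is the genetic share of it
            ratios.append(np.var(truth.true_breeding_values) / np.var(means))
        assert abs(np.mean(ratios) - 0.6) < 0.05

    def test_cross_environment_correlation_below_one(self, small_panel):
        geno, _ = small_panel
        truth = simulate_trait(geno, 40, 0.8, seed=5, gxe_ratio=0.3)
        trials, _ = simulate_environment_trials(
            truth, geno.individual_ids, n_env=2, n_rep=1, target_H2=0.7, seed=2)
        wide = trials.pivot_table(index="genotype_id", columns="environment", values="value")
        r = wide.corr().iloc[0, 1]
        assert 0.2 < r < 0.98

    def test_infeasible_H2_rejected(self, small_panel):
        geno, _ = small_panel
        truth = simulate_trait(geno, 40, 0.8, seed=6, gxe_ratio=2.0)
        with pytest.raises(ConfigError, match="infeasible"):
            simulate_environment_trials(truth, geno.individual_ids, n_env=1, n_rep=1,
                                        target_H2=0.9, seed=0)

    def test_deterministic_under_seed(self, small_panel, small_trait):
        geno, _ = small_panel
        a = simulate_environment_trials(small_trait, geno.individual_ids, 2, 1, 0.6, seed=8)
        b = simulate_environment_trials(small_trait, geno.individual_ids, 2, 1, 0.6, seed=8)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])


def test_inject_missing_rate(small_panel):
    geno, _ = small_panel
    out = inject_missing(geno, 0.1, seed=3)
    frac = np.mean(~np.isfinite(out.dosages))
    assert 0.08 < frac < 0.12
    np.testing.assert_array_equal(out.dosages[np.isfinite(out.dosages)],
                                  geno.dosages[np.isfinite(out.dosages)])
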