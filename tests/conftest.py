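import numpy as np
import pandas as pd
import pytest

from gsel import SimConfig, simulate_genotypes, simulate_trait


@pytest.fixture(scope="session")
def small_panel():
    """120 individuals x 600 markers with moderate LD."""
    return simulate_genotypes(
        SimConfig(n_individuals=120, n_chromosomes=4, markers_per_chromosome=150,
                  chromosome_length_bp=3_000_000, ld_decay_rho=0.8, seed=11)
    )


@pytest.fixture(scope="session")
def small_trait(small_panel):
    geno, _ = small_panel
    return simulate_trait(geno, n_qtl=60, target_h2=0.5, seed=17)


@pytest.fixture(scope="session")
def small_pheno(small_panel, small_trait):
    geno, _ = small_panel
    return pd.Series(small_trait.phenotype, index=geno.individual_ids)


@pytest.fixture()
def toy_genotype():
    """5 x 4 complete toy dosage matrix."""
    from gsel import GenotypeMatrix

    dosages = np.array(
        [
            [0, 1, 2, 1],
            [1, 1, 0, 2],
            [2, 0, 1, 0],
            [0, 2, 2, 1],
            [1, 0, 0, 1],
        ],
        dtype=float,
    )
    return GenotypeMatrix([f"s{i}" for i in range(5)], [f"m{j}" for j in range(4)], dosages)
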