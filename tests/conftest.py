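import numpy as np
import pytest

from refpop import simdata


@pytest.fixture(scope="session")
def small_sim():
    """Fast toy population: 60 founders + 4 families, 3 chromosomes."""
    cfg = simdata.SimConfig(
        n_accessions=60, origin_counts={"A": 30, "B": 30}, n_families=4,
        progeny_per_family=5, n_chromosomes=3, n_snps_full=600,
        n_snps_scaffold=60, chrom_length_bp=400_000, seed=1, n_environments=3,
    )
    return simdata.simulate_population(cfg)


@pytest.fixture(scope="session")
def study_sim():
    """Study-scale population: 269 accessions + 27 families x 10 progeny,
    5 environments x 2 complete blocks, harvest-like trait (G 0.74 / E 0.05 /
    GxE 0.12 / spatial 0.04 / residual 0.05), seed 11."""
    cfg = simdata.SimConfig(
        n_snps_full=5_000, n_snps_scaffold=500, n_environments=5, seed=11,
        trait_specs=[simdata.TraitSpec("harvest")],
    )
    return simdata.simulate_population(cfg)


@pytest.fixture(scope="session")
def desk_sim():
    """Desk-scale default panel: ~540 genotypes x 20,000 SNPs, seed 1."""
    return simdata.simulate_population(simdata.SimConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
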