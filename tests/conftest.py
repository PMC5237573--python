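import numpy as np
import pytest

import dombayes as db


@pytest.fixture(scope="session")
def small_pop() -> db.Population:
    """A cheap population for unit tests: short history, small genome.

    Equilibrium founders at Ne = 80 with a 20-Mb / 0.1-Morgan chromosome
    give a few hundred segregating sites in seconds.
    """
    cfg = db.DemographyConfig(
        n_generations=80,
        ne_schedule=np.full(80, 80, dtype=np.int64),
        final_sample_n=200,
        physical_length=2e7,
        genetic_length=0.1,
        mutation_rate=1e-8,
        seed=42,
        max_sites=20_000,
    )
    return db.simulate_population(cfg)


@pytest.fixture(scope="session")
def small_rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
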