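import numpy as np
import pytest

from imputeval import (
    MarkerMap,
    SimulationConfig,
    prepare_dataset,
    simulate_population,
)


def uniform_map(n_markers: int, spacing_bp: int = 10_000) -> MarkerMap:
    """Evenly spaced marker map starting at 1 bp."""
    return MarkerMap(
        chromosome_id="1",
        positions_bp=np.arange(n_markers, dtype=np.int64) * spacing_bp + 1,
    )


@pytest.fixture(scope="session")
def default_population():
    """One equilibrium population at the package's default conditions."""
    return simulate_population(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    """A compact sampled dataset for imputation and evaluation tests."""
    cfg = SimulationConfig(
        population_size_diploid=60,
        n_generations=200,
        chromosome_length_bp=5_000_000,
        n_candidate_sites=1500,
        mutation_rate=1e-7,
        n_sample_individuals=30,
        seed=11,
    )
    return prepare_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
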