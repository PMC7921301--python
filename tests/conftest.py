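import numpy as np
import pytest

from lolium.simulate import GeneratorConfig, generate_plants


@pytest.fixture(scope="session")
def default_plants():
    """One default-design synthetic dataset (38 genotypes x 2 x 5)."""
    return generate_plants(seed=1)


@pytest.fixture(scope="session")
def big_plants():
    """A large sample for population-level (Monte-Carlo) checks."""
    cfg = GeneratorConfig(
        n_genotypes=500,
        status_counts={"cultivar": 500},
        plants_per_genotype_per_treatment=10,
    )
    return generate_plants(cfg, seed=11)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (order-independent)."""
    return np.random.default_rng(1234)
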