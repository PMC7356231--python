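import pytest

from ampfam.simulate import FamilyParams, simulate_family


@pytest.fixture(scope="session")
def small_family():
    """Three-individual synthetic family shared across tests (seed 1)."""
    params = FamilyParams(n_individuals=3, seed=1)
    genomes, truth = simulate_family(params)
    return params, genomes, truth


@pytest.fixture(scope="session")
def default_family():
    """Full 16-individual default family (seed 1)."""
    params = FamilyParams(seed=1)
    genomes, truth = simulate_family(params)
    return params, genomes, truth
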