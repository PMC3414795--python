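import pytest

from twolib import LibraryPair, SyntheticScenario, simulate_counts


@pytest.fixture
def equal_libs() -> LibraryPair:
    return LibraryPair(10**6, 10**6)


@pytest.fixture
def unequal_libs() -> LibraryPair:
    return LibraryPair(10**6, 3 * 10**6)


@pytest.fixture
def null_scenario() -> SyntheticScenario:
    """1000 genes, equal libraries, no differential expression."""
    return SyntheticScenario(
        n_genes=1000, lib_size_a=500_000, lib_size_b=500_000, de_fraction=0.0, seed=1
    )


@pytest.fixture
def null_run(null_scenario):
    return simulate_counts(null_scenario)
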