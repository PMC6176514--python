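import pytest

from riskloop import LandscapeConfig, analyze_truth, simulate_landscape


@pytest.fixture(scope="session")
def small_truth():
    """Desk-scale labeled landscape shared across tests (fixed seed)."""
    return simulate_landscape(LandscapeConfig.small(), seed=11)


@pytest.fixture(scope="session")
def small_result(small_truth):
    return analyze_truth(small_truth)


@pytest.fixture(scope="session")
def full_truth():
    """Full-scale landscape with the generator's default planted strata."""
    return simulate_landscape(seed=1)


@pytest.fixture(scope="session")
def full_result(full_truth):
    return analyze_truth(full_truth)
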