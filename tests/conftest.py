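import pytest

from mitoproteome import SimulationConfig, generate_proteome, simulate_observations


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_proteins=200, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_proteome(small_config)


@pytest.fixture(scope="session")
def small_observations(small_config, small_truth):
    return simulate_observations(small_truth, small_config)


@pytest.fixture(scope="session")
def noiseless_config():
    """Exact zero-noise limit with full detection and no truncation/coverage loss."""
    return SimulationConfig(
        n_proteins=120,
        seed=3,
        intensity_log_sd=0.0,
        base_log10_sd=0.0,
        missing_rate=0.0,
        detectability=1.0,
        truncation_prob=0.0,
        reference_coverage=1.0,
    )
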