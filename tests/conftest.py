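import pytest

from plantdiet import SimulationConfig, build_profiles, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_participants=800, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_profiles(small_dataset):
    return build_profiles(small_dataset.recalls).drop(columns=["baseline_year"])
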