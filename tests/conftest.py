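import pytest

from circmir.sim import SimConfig, simulate_references


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale two-library configuration with error-free reads."""
    return SimConfig(
        seed=42,
        n_reads={"serum": 4000, "plasma": 4000},
        n_mirnas=40,
        error_rate=0.0,
        min_cpm=2000.0,
        abundance_sigma=0.5,
    )


@pytest.fixture(scope="session")
def small_refs(small_config):
    return simulate_references(small_config)
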