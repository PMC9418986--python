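import numpy as np
import pytest

from mortdiv import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """A quick five-year scenario, large enough that every stratum has deaths."""
    cfg = ScenarioConfig(
        n_zones=20,
        mean_zone_population=5000,
        n_causes=30,
        year_start=2001,
        year_end=2005,
        seed=42,
    )
    zones, population, deaths = generate_scenario(cfg)
    return cfg, zones, population, deaths


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
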