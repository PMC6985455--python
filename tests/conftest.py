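import numpy as np
import pytest

from cinsynergy import SimConfig, simulate_screen


@pytest.fixture(scope="session")
def small_config():
    """A compact 4-day screen: 2 lines x (vehicle + 1 drug), no passage."""
    return SimConfig(
        genotype_penalty={"RPE1": 1.0, "RPE1_Mad2cKD": 0.75},
        drug_effect={"DMSO": 1.0, "drugA": 0.8},
        duration_h=96.0,
        passage_day=None,
        seed=1234,
    )


@pytest.fixture(scope="session")
def small_screen(small_config):
    table, gt = simulate_screen(config=small_config)
    return table, gt


@pytest.fixture(scope="session")
def default_screen():
    """The full default design: 8 days, passage on day 4."""
    cfg = SimConfig(seed=99)
    table, gt = simulate_screen(config=cfg)
    return cfg, table, gt


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
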