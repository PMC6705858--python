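import numpy as np
import pytest

from pinfish.simulate import EstuaryConfig, MetapopConfig, simulate_survey


@pytest.fixture(scope="session")
def small_survey():
    """A compact default-structure survey: 2 estuaries, 4 years."""
    cfg = MetapopConfig(
        estuaries=[
            EstuaryConfig(estuary="AB", density_scale=23.0),
            EstuaryConfig(estuary="TB", density_scale=40.0),
        ],
        years=(2000, 2003),
        hauls_per_month=(9, 12),
        lag_months={"AB": 1.0},
        seed=42,
    )
    table, truth = simulate_survey(cfg)
    return cfg, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
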