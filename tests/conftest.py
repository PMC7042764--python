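import numpy as np
import pandas as pd
import pytest

from birdipm import synthetic_data as sd


@pytest.fixture(scope="session")
def reduced_sim():
    """One reduced-scenario simulated dataset shared across tests."""
    return sd.simulate_dataset(sd.reduced_scenario(), seed=20_240)


@pytest.fixture(scope="session")
def reduced_dataset(reduced_sim):
    return reduced_sim.assemble()


@pytest.fixture
def tiny_counts_frame():
    return pd.DataFrame(
        {
            "route_observer": ["r1_o1"] * 3,
            "route": ["r1"] * 3,
            "stratum": ["s1"] * 3,
            "year": [2000, 2001, 2002],
            "count": [3, 0, 5],
            "novice": [1, 0, 0],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
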