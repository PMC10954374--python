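import numpy as np
import pandas as pd
import pytest

from diatombiogeo import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact but complete synthetic study used across test modules."""
    cfg = SimulationConfig(n_sites=80, n_species=50, structure="gleasonian", seed=42)
    return generate_dataset(cfg)


@pytest.fixture()
def community_5x7():
    """Hand-readable 5-site, 7-species incidence fixture."""
    data = np.array([
        [1, 1, 0, 0, 1, 0, 0],
        [1, 0, 1, 0, 0, 0, 0],
        [0, 1, 1, 1, 0, 0, 0],
        [0, 0, 0, 1, 1, 1, 0],
        [1, 0, 0, 0, 0, 1, 1],
    ])
    return pd.DataFrame(
        data,
        index=[f"s{i}" for i in range(5)],
        columns=[f"sp{j}" for j in range(7)],
    )
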