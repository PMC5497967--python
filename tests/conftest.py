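import numpy as np
import pytest

from afnet import (
    KSGParameters,
    SimulationConfig,
    add_ventricular_farfield,
    generate_basket_layout,
    generate_planted_network,
    simulate_coupled_af,
)


@pytest.fixture(scope="session")
def small_layout():
    return generate_basket_layout(2, 3)  # 6 channels


@pytest.fixture(scope="session")
def small_truth(small_layout):
    # one planted pair among 6 channels, strong coupling
    import numpy as np

    adj = np.zeros((6, 6), dtype=int)
    adj[0, 1] = adj[1, 0] = 1
    from afnet import GroundTruthNetwork

    return GroundTruthNetwork(adj, adj * 0.8)


@pytest.fixture(scope="session")
def short_cfg():
    # 12 s keeps unit tests fast; windowing tests use their own configs
    return SimulationConfig(duration_s=12.0, seed=42)


@pytest.fixture(scope="session")
def small_recording(small_layout, small_truth, short_cfg):
    return simulate_coupled_af(small_layout, small_truth, short_cfg)


@pytest.fixture(scope="session")
def contaminated(small_recording, short_cfg):
    return add_ventricular_farfield(small_recording, short_cfg)


@pytest.fixture(scope="session")
def ksg_params():
    return KSGParameters(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
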