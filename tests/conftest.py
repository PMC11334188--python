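import numpy as np
import pytest

import platecal as pc


@pytest.fixture(scope="session")
def linear_map():
    return pc.build_linear_map()


@pytest.fixture(scope="session")
def linear_instructions(linear_map):
    return pc.linear_transfer_instructions(linear_map)


@pytest.fixture(scope="session")
def geometric_map():
    return pc.build_geometric_map()


@pytest.fixture(scope="session")
def geometric_instructions(geometric_map):
    return pc.geometric_transfer_instructions(geometric_map)


@pytest.fixture(scope="session")
def ideal_linear_sim(linear_map, linear_instructions):
    """Noiseless, error-free simulated linear plate (single repeat)."""
    return pc.simulate_plate(linear_map, linear_instructions)


@pytest.fixture(scope="session")
def ideal_geometric_sim(geometric_map, geometric_instructions):
    return pc.simulate_plate(geometric_map, geometric_instructions)


def target_vector(plate_map, wells):
    return np.array([plate_map[w].target_ratio for w in wells])
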