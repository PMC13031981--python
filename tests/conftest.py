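import numpy as np
import pytest

from microzoo import synthetic


@pytest.fixture(scope="session")
def default_scenario_table():
    """A seeded community table under the default seasonal scenario."""
    scenario = synthetic.default_scenario(seed=7)
    return scenario, synthetic.gen_community_table(scenario)


@pytest.fixture(scope="session")
def noiseless_cell_field():
    """20 non-overlapping dinoflagellates rendered without noise."""
    scale = 0.125
    specs = synthetic.random_cell_specs(
        20, (2048, 2048), scale, seed=11, size_range_um=(5.0, 60.0),
        ciliate_prob=0.0,
    )
    image, truth = synthetic.gen_micrograph(specs, (2048, 2048), scale)
    return image, truth, scale


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
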