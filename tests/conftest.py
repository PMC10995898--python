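import numpy as np
import pytest

from dnuptake import synthetic


@pytest.fixture(scope="session")
def default_field():
    """One simulated three-channel field under the default study conditions."""
    spec = synthetic.CellImageSpec(seed=11)
    surface, internal, nuclear, truth = synthetic.make_cell_image(spec)
    return spec, surface, internal, nuclear, truth


@pytest.fixture(scope="session")
def noise_free_field():
    """Same field with noise and offset disabled: sums must equal truths."""
    spec = synthetic.CellImageSpec(seed=11, noise_model="none",
                                   background_offset=0.0)
    surface, internal, nuclear, truth = synthetic.make_cell_image(spec)
    return spec, surface, internal, nuclear, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
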