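import numpy as np
import pytest

from qibcdeg.synthetic_data import FieldSpec, make_cell_population, render_field


@pytest.fixture(scope="session")
def noiseless_field():
    """A small noiseless rendered field with its population and truth mask."""
    cells = make_cell_population(40, seed=11, field_shape=(420, 420), margin=24)
    spec = FieldSpec(width=420, height=420, noise_sd=0.0, seed=11)
    channels, truth = render_field(cells, spec)
    return cells, spec, channels, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
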