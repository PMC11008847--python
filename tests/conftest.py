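import numpy as np
import pytest

from epilayer import ModelParams, make_circular_cell


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20240401)


def star_polygon(rng, n=12, base_radius=1.0, wobble=0.3, center=(0.0, 0.0)):
    """Random star-shaped (hence simple) polygon around a circle."""
    theta = np.sort(rng.uniform(0, 2 * np.pi, n))
    # enforce distinct angles
    theta += np.linspace(0, 1e-3, n)
    r = base_radius * (1.0 + wobble * rng.uniform(-1, 1, n))
    return np.column_stack([center[0] + r * np.cos(theta),
                            center[1] + r * np.sin(theta)])


@pytest.fixture
def unit_cell():
    return make_circular_cell((0.0, 2.0), 1.0, 100)
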