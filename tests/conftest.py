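import numpy as np
import pytest

from wlsfem import build_box_mesh


@pytest.fixture(scope="session")
def unit_square_2x2():
    return build_box_mesh([1.0, 1.0], [2, 2])


@pytest.fixture(scope="session")
def unit_cube_1():
    return build_box_mesh([1.0, 1.0, 1.0], [1, 1, 1])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
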