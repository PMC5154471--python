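import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20160)


@pytest.fixture
def small_grid():
    from hybridrd import build_box_grid
    return build_box_grid([[0.0, 1.0], [0.0, 1.0], [0.0, 1.0]],
                          (0.25, 0.25, 0.25))
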