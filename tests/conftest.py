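import numpy as np
import pytest

from protonpath import PathNodes, resample_equidistant, set_frame


@pytest.fixture
def straight_nodes() -> PathNodes:
    """25 equidistant nodes on the x axis, spacing 1 A, origin at index 12."""
    line = np.array([[0.0, 0.0, 0.0], [24.0, 0.0, 0.0]])
    return set_frame(resample_equidistant(line, 25), origin_index=12, orientation=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
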