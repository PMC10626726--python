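import numpy as np
import pytest

from corolabel import generate_case, rasterize
from corolabel.pipeline import graph_from_mask


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


@pytest.fixture(scope="session")
def default_case():
    return generate_case(42)


@pytest.fixture(scope="session")
def default_graph(default_case):
    return graph_from_mask(rasterize(default_case))
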