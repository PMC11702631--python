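import numpy as np
import pytest

from cogmorph.surface import build_icosphere, make_medial_wall


@pytest.fixture(scope="session")
def mesh3():
    """ico3 mesh (642 vertices/hemi) with a 5% medial wall."""
    return make_medial_wall(build_icosphere(3), 0.05)


@pytest.fixture(scope="session")
def mesh4():
    """ico4 mesh (2562 vertices/hemi) with a 5% medial wall; the default
    analysis substrate."""
    return make_medial_wall(build_icosphere(4), 0.05)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
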