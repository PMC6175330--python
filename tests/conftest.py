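import numpy as np
import pytest

from mvpasim import make_block_design


@pytest.fixture(scope="session")
def default_design():
    """The study layout: 16 s blocks, 8 blocks/subrun, 4 subruns, 2 s samples."""
    return make_block_design()


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
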