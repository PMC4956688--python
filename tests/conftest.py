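import numpy as np
import pytest

from mvlight import make_toy_fmri, make_toy_meeg


@pytest.fixture
def meeg_ds():
    """18 planar channels x 5 time points, 3 targets x 4 chunks."""
    return make_toy_meeg(seed=11)


@pytest.fixture
def fmri_ds():
    """Small 6x6x6 volume with a planted central signal region."""
    return make_toy_fmri(dim=(6, 6, 6), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
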