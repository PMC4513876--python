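import numpy as np
import pytest
from hypothesis import settings

from phagetrans import CapsidModel, get_preset

settings.register_profile("det", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("det")


@pytest.fixture
def wt() -> object:
    return get_preset("WT_Mg10")


@pytest.fixture
def wt_noiseless(wt):
    return wt.noiseless()


@pytest.fixture
def l78_noiseless():
    return get_preset("L78_Mg10").noiseless()


@pytest.fixture
def capsid() -> CapsidModel:
    return CapsidModel()


@pytest.fixture
def itc_grid() -> np.ndarray:
    """The measured ITC temperature grid: 18-42 C in 2 C steps."""
    return np.arange(18.0, 43.0, 2.0)
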