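import numpy as np
import pytest

from mrcyt import FitConfig, default_protocol
from mrcyt.fitting import make_fit_context


@pytest.fixture(scope="session")
def protocol():
    """The three-sequence protocol at full waveform resolution."""
    return default_protocol()


@pytest.fixture(scope="session")
def fit_context(protocol):
    """Shared fitting context (coarse waveform grid, LHS starts)."""
    return make_fit_context(protocol, FitConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
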