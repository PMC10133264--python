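import numpy as np
import pytest

from seegflow.core import TrialTensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tensor(data, fs=1000.0, onset_index=1000, **kw) -> TrialTensor:
    return TrialTensor(data=np.asarray(data, float), fs=fs,
                       onset_index=onset_index, **kw)


@pytest.fixture
def white_tensor(rng):
    """4 leads x 24 trials x 2000 samples of unit white noise."""
    return make_tensor(rng.standard_normal((4, 24, 2000)))
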