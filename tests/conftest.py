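import numpy as np
import pytest

from vcephys import CellGroundTruth, Sweep


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_cell():
    """Noiseless ground truth with negligible evoked spiking."""
    return CellGroundTruth(noise_sd=0.0, r_max=1e-9)


def flat_sweep(value_mv=-75.0, duration_ms=1000.0, fs=10000.0, **kw):
    n = int(round(duration_ms * fs / 1000.0))
    return Sweep(vm=np.full(n, value_mv), fs=fs, **kw)


@pytest.fixture
def make_flat_sweep():
    return flat_sweep
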