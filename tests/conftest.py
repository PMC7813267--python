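import numpy as np
import pytest

from erpwp.preprocess import Epochs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_epochs(data, channels=("Fz", "Cz"), fs=1000.0, conditions=None,
                tmin_ms=-200.0):
    """Build an Epochs object around a raw (trials, channels, samples)
    array with a standard time axis."""
    data = np.asarray(data, dtype=float)
    n_trials, n_ch, n_samp = data.shape
    times = tmin_ms + np.arange(n_samp) * 1000.0 / fs
    if conditions is None:
        conditions = np.array(
            ["WORDS", "SIMILAR", "NONSENSE"] * ((n_trials + 2) // 3)
        )[:n_trials]
    return Epochs(data, channels, times, conditions, fs)


@pytest.fixture()
def small_epochs(rng):
    return make_epochs(rng.normal(0, 10, (12, 2, 300)))
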