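import numpy as np
import pytest

from bandnet.signals import SignalSet, default_channel_meta


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def noise_signals(rng):
    """8 channels of 10 s independent white noise at 500 Hz."""
    data = rng.standard_normal((8, 5000))
    return SignalSet(
        data=data,
        sampling_rate=500.0,
        channels=default_channel_meta(8),
        subject_id="noise-01",
        group="test",
    )


def make_signals(data, fs=500.0, **kw):
    data = np.atleast_2d(np.asarray(data, float))
    return SignalSet(
        data=data,
        sampling_rate=fs,
        channels=default_channel_meta(data.shape[0]),
        **kw,
    )
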