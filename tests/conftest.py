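import numpy as np
import pytest

from eegic.ic_model import ICComponent
from eegic.montage import DEFAULT_MONTAGE


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_component(component_id="c0", weights=None, signal=None,
                   channels=None, fs=250.0, rng=None):
    """Small valid component with sensible defaults for unit tests."""
    channels = list(channels) if channels is not None else list(DEFAULT_MONTAGE)
    if weights is None:
        local = rng or np.random.default_rng(0)
        weights = local.normal(size=len(channels))
    if signal is None:
        local = rng or np.random.default_rng(1)
        signal = local.normal(size=(5, 128))
    return ICComponent(component_id=component_id, subject_id="s01",
                       channel_labels=channels, weights=weights,
                       signal=signal, sampling_rate=fs)


@pytest.fixture
def component():
    return make_component()
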