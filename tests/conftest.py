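import numpy as np
import pytest

from hiephys.io import SpikeTrain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_train(times, duration, unit_id="u0", region="RSC", group="sham_left"):
    return SpikeTrain(unit_id, region, group, np.asarray(times, dtype=float),
                      duration)


@pytest.fixture
def periodic_train():
    """10 Hz perfectly periodic unit over 100 s."""
    return make_train(np.arange(1, 991) * 0.1, 100.0)
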