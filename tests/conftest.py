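import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import smiband as sb

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_scene():
    """The benchmark scene: 6 redundancy groups x 5 bands, 5 classes, 5% noise."""
    return sb.simulate(sb.SynthConfig(seed=0))


@pytest.fixture(scope="session")
def small_scene():
    """A fast scene for I/O and CLI-level tests."""
    cfg = sb.SynthConfig(height=24, width=24, n_classes=3, n_groups=3,
                         bands_per_group=2, seed=7)
    return sb.simulate(cfg)
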