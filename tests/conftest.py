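import numpy as np
import pytest

from aquachroma.bench import BenchConfig
from aquachroma.camera import default_cameras


@pytest.fixture(scope="session")
def cfg():
    return BenchConfig()


@pytest.fixture(scope="session")
def cameras():
    return default_cameras()


@pytest.fixture(scope="session")
def grid():
    return np.arange(380.0, 781.0, 5.0)


@pytest.fixture(scope="session")
def scene(cameras):
    """A small rendered scene: chart + blank + mid-concentration cuvettes."""
    from aquachroma.bench import capture_scene
    from aquachroma.optics import SampleComposition

    samples = [
        SampleComposition(cdom_concentration=0.0),
        SampleComposition(cdom_concentration=60.0),
    ]
    return capture_scene(samples, cameras[0], level=1010.0, seed=7)
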