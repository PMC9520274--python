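import numpy as np
import pytest

from sonokit import AcousticDrive, BubbleSystem, default_system


@pytest.fixture(scope="session")
def system() -> BubbleSystem:
    """Frozen default parameter set."""
    return default_system()


@pytest.fixture()
def drive_off() -> AcousticDrive:
    return AcousticDrive(center_frequency=250e3, peak_negative_pressure=0.0,
                         n_cycles=50)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
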