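import numpy as np
import pytest

from drivestyle.defaults import STYLES
from drivestyle.synthetic import DrivingGroupSpec, EEGGroupSpec, generate_eeg_recording


@pytest.fixture(scope="session")
def driving_specs():
    return [DrivingGroupSpec.from_defaults(s) for s in STYLES]


@pytest.fixture(scope="session")
def conservative_eeg_spec():
    return EEGGroupSpec.from_defaults("Conservative")


@pytest.fixture(scope="session")
def clean_recording(conservative_eeg_spec):
    """One artifact-free Conservative-profile recording (30 s at 256 Hz)."""
    return generate_eeg_recording(
        conservative_eeg_spec, duration_s=30.0, fs=256.0, seed=7, with_artifacts=False
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
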