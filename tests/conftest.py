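import numpy as np
import pytest

from anklemg.harness import build_window_dataset
from anklemg.synthetic_data import ActivationProfile, ProtocolSpec, generate_dataset


@pytest.fixture(scope="session")
def small_trials():
    """One synthetic subject, 2 repetitions: 36 trials across all loads/movements."""
    protocol = ProtocolSpec(repetitions=2)
    return generate_dataset(n_subjects=1, protocol=protocol, seed=20240915)


@pytest.fixture(scope="session")
def small_windows(small_trials):
    """Window dataset of the small trial set: 36 x 29 = 1,044 windows."""
    return build_window_dataset(small_trials)


@pytest.fixture
def quiet_profile():
    """Interference-free, baseline-free profile for clean amplitude checks."""
    return ActivationProfile(interference_uv=0.0, baseline_uv=0.0)


@pytest.fixture
def fast_protocol():
    """Short phases so per-trial generation stays cheap."""
    return ProtocolSpec(rest_s=0.05, motion_s=0.1, hold_s=0.1, trim_ms=0.0,
                       repetitions=1)
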