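"""Shared fixtures: small synthetic recordings generated at test time."""

import numpy as np
import pytest

from mrcp import synthgen


@pytest.fixture(scope="session")
def small_session():
    """Five-trial session at full 1024 Hz (EMG-capable)."""
    return synthgen.make_session(
        profile=synthgen.SubjectProfile(seed=7), n_trials=5, fs=1024.0
    )


@pytest.fixture(scope="session")
def eeg_session_128():
    """Five-trial session at 128 Hz for EEG-side tests (fast)."""
    return synthgen.make_session(
        profile=synthgen.SubjectProfile(seed=11), n_trials=5, fs=128.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
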