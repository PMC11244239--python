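import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from strokeeg.preprocess import bandpass_filter, segment
from strokeeg.synth import SynthConfig, generate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def coupled_recording():
    """Strongly coupled noise-free subject: every pair phase-locked."""
    cfg = SynthConfig(duration_s=20.0, coupling_control=1.0, coupling_stroke=1.0,
                      complexity_control=0.0, complexity_stroke=0.0,
                      noise_sd=0.0, subject_coupling_sd=0.0,
                      confound_coupling_sd=0.0,
                      subject_complexity_rel_sd=0.0, seed=1)
    return generate_subject(cfg, 0)


@pytest.fixture(scope="session")
def coupled_epochs(coupled_recording):
    return segment(bandpass_filter(coupled_recording), 1.0)


@pytest.fixture(scope="session")
def realistic_recording():
    """Default-condition control subject (coupling 0.6, complexity 1.0)."""
    return generate_subject(SynthConfig(duration_s=12.0, seed=2), 0)
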