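import numpy as np
import pytest

from wheelwiggle.synthetic import SessionSpec, generate_session


@pytest.fixture(scope="session")
def small_session():
    """A compact full-featured synthetic session (traces, spikes, pupil)."""
    spec = SessionSpec(
        n_trials=120, seed=11, n_neurons=8, coding_strength=0.5,
        pupil_coupling=0.0, p_false_start=0.05,
    )
    return generate_session(spec)


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free session with no false starts, for ground-truth closure."""
    spec = SessionSpec(
        n_trials=60, seed=23, p_false_start=0.0, noise_frac=0.0,
    )
    return generate_session(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
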