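import numpy as np
import pytest

from cardiorisk.simulate import simulate_cohort, simulate_ecg


@pytest.fixture(scope="session")
def clean_ecg():
    """Noise-free 60 bpm fixture: 10 s at 350 Hz, flat ST."""
    return simulate_ecg(fs=350, duration=10, hr_bpm=60, st_slope=0.0,
                        noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def long_ecg():
    """Noise-free 60-beat fixture with an injected ST ramp."""
    return simulate_ecg(fs=350, duration=60, hr_bpm=60, st_slope=0.003,
                        noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def separated_cohort():
    """Fully observed cohort with 3-pooled-SD class separation."""
    return simulate_cohort(n=600, class_proportions=(0.45, 0.28, 0.27),
                           effect_size=3.0, missing_rate=0.0, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
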