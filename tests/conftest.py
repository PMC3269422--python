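import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def freq_axis_32():
    return np.geomspace(180.0, 7000.0, 32)


@pytest.fixture(scope="session")
def am_tone_spectrogram():
    """128-channel spectrogram of a 2 s, 4 Hz amplitude-modulated 1 kHz tone."""
    from speechdecode import compute_auditory_spectrogram
    from speechdecode.synthetic_data import generate_stimuli

    w = generate_stimuli(
        "am_tone", {"carrier_hz": 1000.0, "rate_hz": 4.0, "duration_s": 2.0}, 1, 0
    )[0]
    return compute_auditory_spectrogram(w)


@pytest.fixture(scope="session")
def word_spectrogram_32():
    """32-channel spectrogram of one synthetic word (1 s)."""
    from speechdecode import compute_auditory_spectrogram, downsample_spectrogram
    from speechdecode.synthetic_data import generate_stimuli

    w = generate_stimuli("formant_word", {"duration_s": 1.0}, 1, 3)[0]
    return downsample_spectrogram(compute_auditory_spectrogram(w))


@pytest.fixture(scope="session")
def energy_dataset():
    """Purely modulation-energy population over 20 synthetic words."""
    from speechdecode.synthetic_data import make_benchmark

    ds, _ = make_benchmark(
        "energy", seed=5, n_stimuli=20, stimulus_params={"duration_s": 0.8}
    )
    return ds


@pytest.fixture(scope="session")
def envelope_dataset():
    """Purely envelope-locked population over 16 synthetic words."""
    from speechdecode.synthetic_data import make_benchmark

    ds, _ = make_benchmark(
        "envelope", seed=9, n_stimuli=16, n_units=10,
        stimulus_params={"duration_s": 0.8}, noise_sd=0.05,
    )
    return ds
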