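import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sine_recording():
    """Two-channel recording: a 10 Hz tone and a 50 Hz tone, fs=256, 20 s."""
    from stressfs import EEGRecording

    fs = 256.0
    t = np.arange(0, 20, 1 / fs)
    data = np.vstack([np.sin(2 * np.pi * 10 * t), np.sin(2 * np.pi * 50 * t)])
    return EEGRecording(data, fs, ("tone10", "tone50"))


@pytest.fixture(scope="session")
def small_epochs():
    """Fast 4-channel synthetic epoch set with a class contrast."""
    from stressfs import SyntheticSpec, generate_eeg

    return generate_eeg(
        SyntheticSpec(
            n_channels=4,
            fs=128.0,
            window_s=3.0,
            n_epochs_per_class=4,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def planted_small():
    """Planted table used across mRMR/PSO tests (3 informative, 9 noise)."""
    from stressfs import PlantedTableSpec, generate_table

    return generate_table(
        PlantedTableSpec(
            n_rows=80,
            n_informative=3,
            n_redundant=0,
            n_noise=9,
            effect_size=1.2,
            seed=5,
        )
    )
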