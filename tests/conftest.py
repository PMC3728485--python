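import numpy as np
import pytest
from hypothesis import settings

from icdecode import synth
from icdecode.eeg import EpochSet

settings.register_profile("ci", derandomize=True, max_examples=30,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_eeg():
    """Quick EEG dataset: 8 channels, 20 trials/class, one discriminative
    gamma source, modest noise."""
    cfg = synth.EEGSimConfig(
        n_trials_per_class=20,
        noise_sd=0.5,
        sources=[
            synth.SourceSpec(center_freq=30.0, band="gamma", latency_B=600.0,
                             latency_DB=1178.0, amplitude=2.5),
        ],
        seed=42,
    )
    epochs, truth = synth.simulate_eeg(cfg)
    return cfg, epochs, truth


@pytest.fixture(scope="session")
def noiseless_eeg3():
    """Noise-free EEG with three sources (for exact linear-mixture checks)."""
    cfg = synth.EEGSimConfig(n_trials_per_class=15, noise_sd=0.0, seed=7)
    epochs, truth = synth.simulate_eeg(cfg)
    return cfg, epochs, truth


@pytest.fixture(scope="session")
def small_fmri():
    cfg = synth.FMRISimConfig(seed=5, noise_sd=0.1)
    vol, truth = synth.simulate_fmri(cfg)
    return cfg, vol, truth


@pytest.fixture()
def flat_epochs():
    """All-zero epochs for artifact-detection edge cases."""
    return EpochSet(data=np.zeros((20, 8, 750)),
                    labels=np.array(["B", "DB"] * 10),
                    sampling_rate=250.0, t0_offset=-500.0)
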