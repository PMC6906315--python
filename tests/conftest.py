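import pytest

from enscode.synthdata import SimConfig, generate_stimuli, simulate_epochs


@pytest.fixture(scope="session")
def small_noiseless():
    """Noiseless stable-regime SO epochs on a short 100 Hz grid."""
    cfg = SimConfig(n_trials_so=48, n_trials_vo=48, n_electrodes=12,
                    sampling_rate=100.0, epoch_window=(-0.1, 0.2),
                    noise_sd=0.0, seed=1)
    stim = generate_stimuli(48, "SO", 1, seed=0, balanced=True)
    return simulate_epochs(stim, cfg)


@pytest.fixture(scope="session")
def small_noisy():
    """Moderate-noise stable-regime SO epochs for statistical checks."""
    cfg = SimConfig(n_trials_so=64, n_trials_vo=48, n_electrodes=12,
                    sampling_rate=100.0, epoch_window=(-0.1, 0.3),
                    noise_sd=1.0, seed=2)
    stim = generate_stimuli(64, "SO", 1, seed=5, balanced=True)
    return simulate_epochs(stim, cfg)


def decode_cfg(**overrides):
    """Short-epoch generator settings shared by decoding tests."""
    base = dict(n_trials_so=48, n_trials_vo=48, n_electrodes=12,
                sampling_rate=100.0, epoch_window=(-0.1, 0.3),
                noise_sd=1.0, seed=0)
    base.update(overrides)
    return SimConfig(**base)
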