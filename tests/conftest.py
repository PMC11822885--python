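import numpy as np
import pytest

import intentdecode as itd


def make_dataset(**kwargs):
    cfg = itd.SimulationConfig(**kwargs)
    rec, events, truth = itd.generate_recording(cfg)
    return cfg, rec, events, truth


def hg_envelope(rec):
    spec = itd.design_band_filter(rec.sampling_rate, itd.BANDS["high_gamma"])
    return itd.band_power(rec, spec)


@pytest.fixture(scope="session")
def signal_dataset():
    """High-SNR fixture: 4 production, 2 perception, 2 silent channels."""
    return make_dataset(n_channels=8, n_trials=40, modulation_snr=5.0, seed=101)


@pytest.fixture(scope="session")
def signal_env(signal_dataset):
    _, rec, _, _ = signal_dataset
    return hg_envelope(rec)


@pytest.fixture(scope="session")
def signal_epochs(signal_dataset, signal_env):
    _, _, events, _ = signal_dataset
    return itd.epoch(signal_env, events, align="voice_onset", window=(-1.0, 0.5))


@pytest.fixture(scope="session")
def null_dataset():
    """Zero-SNR fixture: no planted modulation anywhere."""
    return make_dataset(n_channels=8, n_trials=40, modulation_snr=0.0, seed=202)


@pytest.fixture(scope="session")
def null_env(null_dataset):
    _, rec, _, _ = null_dataset
    return hg_envelope(rec)


@pytest.fixture()
def fast_decoder():
    """Small decoder config for unit tests (single grid point, 5 iterations)."""
    return itd.DecoderConfig(
        n_iterations=5,
        n_shuffles=100,
        penalty_grid=(1.0,),
        kernel_width_grid=("1/d",),
        seed=7,
    )
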