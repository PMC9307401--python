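import numpy as np
import pytest

from prestim.containers import EvokedWaveform, RawRecording
from prestim.montage import positions_2d
from prestim.synth import EffectSpec, ExperimentConfig, generate_session

SMALL_CHANNELS = (
    "Fp1", "Fpz", "Fp2", "F3", "Fz", "F4", "Cz", "Pz", "Oz", "VEOG",
)


@pytest.fixture(scope="session")
def small_channels():
    return SMALL_CHANNELS


def make_small_config(**kw) -> ExperimentConfig:
    defaults = dict(
        left_value=25.0,
        n_trials=30,
        sampling_rate=250.0,
        channel_names=SMALL_CHANNELS,
        seed=11,
    )
    defaults.update(kw)
    return ExperimentConfig(**defaults)


@pytest.fixture
def small_config():
    return make_small_config()


@pytest.fixture(scope="session")
def noiseless_session():
    """A clean session: injected templates only, no noise or artifacts."""
    config = make_small_config(n_trials=40, sampling_rate=500.0, seed=5)
    effects = EffectSpec(
        noise_rms_uv=0.0, blink_rate_per_min=0.0, bad_block_rate_per_min=0.0
    )
    return config, effects, generate_session(config, effects)


@pytest.fixture(scope="session")
def noisy_session():
    """A realistic small session with noise, blinks and bad blocks."""
    config = make_small_config(n_trials=40, sampling_rate=250.0, seed=21)
    effects = EffectSpec()
    return config, effects, generate_session(config, effects)


def make_evoked(
    times,
    fz,
    channel_names=("F3", "Fz", "F4"),
    condition="a",
    lock="decision",
    n=10,
    others=0.0,
):
    """Evoked waveform with a prescribed Fz trace (other channels constant)."""
    times = np.asarray(times, dtype=float)
    data = np.full((len(channel_names), times.size), float(others))
    data[list(channel_names).index("Fz")] = np.asarray(fz, dtype=float)
    return EvokedWaveform(
        data=data,
        times=times,
        channel_names=tuple(channel_names),
        n=n,
        condition=condition,
        lock=lock,
    )


def make_raw(data, channel_names, sampling_rate=250.0):
    return RawRecording(
        data=np.asarray(data, dtype=float),
        sampling_rate=sampling_rate,
        channel_names=tuple(channel_names),
        montage_positions=positions_2d(channel_names),
    )
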