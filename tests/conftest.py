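import numpy as np
import pytest

from respemg import envelope as ev
from respemg import features as ft
from respemg import pipelines as pl
from respemg import synthgen
from respemg.signal_core import Recording, Signal

SCENE_SEED = 3  # fixed so every derived assertion is deterministic


@pytest.fixture(scope="session")
def default_scene():
    """The reference contaminated scene (60 s @ 1000 Hz) plus ground truth."""
    return synthgen.default_scene(seed=SCENE_SEED)


@pytest.fixture(scope="session")
def scene_recording(default_scene):
    mixed, _ = default_scene
    return Recording.from_signals([mixed])


@pytest.fixture(scope="session")
def wavelet_result(scene_recording):
    """Wavelet-preset pipeline run on the default scene (shared, expensive)."""
    config = pl.preset_config("wavelet", fs=1000.0)
    return pl.run_pipeline(scene_recording, config)


@pytest.fixture(scope="session")
def fsampen_result(scene_recording):
    config = pl.preset_config("fsampen")
    return pl.run_pipeline(scene_recording, config)


@pytest.fixture(scope="session")
def gating_result(scene_recording):
    config = pl.preset_config("gating")
    return pl.run_pipeline(scene_recording, config)


@pytest.fixture(scope="session")
def clean_envelope_breaths(default_scene):
    """Oracle: the identical RMS-envelope + detection chain run on the clean
    EMG, for onset/offset agreement checks."""
    _, gt = default_scene
    env = ev.moving_rms(gt.clean_emg)
    noise = ev.estimate_noise_floor(env)
    corrected = ev.correct_baseline(env, noise)
    return corrected, ft.detect_breaths(corrected, noise), noise


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def sine(freq_hz: float, fs: float, duration_s: float, amplitude: float = 1.0) -> Signal:
    t = np.arange(int(duration_s * fs)) / fs
    return Signal(amplitude * np.sin(2 * np.pi * freq_hz * t), fs=fs, kind="emg")


@pytest.fixture()
def make_sine():
    return sine
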