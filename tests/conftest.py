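import numpy as np
import pytest

from cryseg.io_formats import AudioRecording
from cryseg.preprocess import FrameMatrix
from cryseg.synthetic import Event, SceneSpec, render_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_frames(frames: np.ndarray, sr: int = 16000, hop: int | None = None) -> FrameMatrix:
    """Wrap a raw (n_frames, frame_len) array as an unwindowed FrameMatrix."""
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    return FrameMatrix(
        frames=frames,
        frame_len_samples=frames.shape[1],
        hop_samples=hop or frames.shape[1],
        sample_rate_hz=sr,
    )


def sine_recording(freq_hz: float, duration_s: float = 1.0, sr: int = 16000,
                   amplitude: float = 0.5) -> AudioRecording:
    t = np.arange(int(duration_s * sr)) / sr
    return AudioRecording(amplitude * np.sin(2 * np.pi * freq_hz * t), sr)


@pytest.fixture
def cry_scene():
    """A clean scene containing only cries and background (no speech/noise)."""
    events = [
        Event("BKG", 1.0, amplitude=0.003),
        Event("EXP", 1.5, 350.0, 450.0, amplitude=0.35),
        Event("INSV", 0.4, 200.0, 210.0, amplitude=0.2),
        Event("EXP", 1.2, 400.0, 380.0, amplitude=0.35),
        Event("BKG", 0.8, amplitude=0.003),
    ]
    return render_scene(SceneSpec(events=events, seed=7))
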