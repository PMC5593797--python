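"""Pre-emphasis, framing and windowing.

The analysis front end applies a first-order high-pass emphasis filter
``y[n] = x[n] - alpha * x[n-1]`` (default alpha 0.97), slices the signal into
overlapping frames (default 30 ms frames with 21 ms overlap, i.e. a 9 ms hop)
and multiplies each frame by a Hamming window before spectral analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_formats import AudioRecording

__all__ = ["FrameMatrix", "preemphasize", "frame_signal", "apply_hamming", "hamming_window"]

DEFAULT_FRAME_LEN_S = 0.030
DEFAULT_OVERLAP_S = 0.021


@dataclass
class FrameMatrix:
    """Overlapping analysis frames of a mono signal.

    ``frames`` is ``n_frames x frame_len_samples``; trailing samples that do
    not fill a whole frame are dropped, so
    ``n_frames = floor((N - frame_len) / hop) + 1``.
    """

    frames: np.ndarray
    frame_len_samples: int
    hop_samples: int
    sample_rate_hz: int
    windowed: bool = False

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_len_s(self) -> float:
        return self.frame_len_samples / self.sample_rate_hz

    @property
    def hop_s(self) -> float:
        return self.hop_samples / self.sample_rate_hz


def preemphasize(rec: AudioRecording, alpha: float = 0.97) -> AudioRecording:
    """High-pass emphasis filter 1 - alpha*z^-1; the first sample is kept."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    x = rec.samples
    if x.ndim != 1:
        raise ValueError("preemphasize expects a mono recording")
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - alpha * x[:-1]
    return AudioRecording(y, rec.sample_rate_hz)


def frame_signal(
    rec: AudioRecording,
    frame_len_s: float = DEFAULT_FRAME_LEN_S,
    overlap_s: float = DEFAULT_OVERLAP_S,
) -> FrameMatrix:
    """Slice a mono recording into overlapping frames (partial tail dropped)."""
    if rec.samples.ndim != 1:
        raise ValueError("frame_signal expects a mono recording")
    if not 0 <= overlap_s < frame_len_s:
        raise ValueError("need 0 <= overlap_s < frame_len_s")
    sr = rec.sample_rate_hz
    frame_len = int(round(frame_len_s * sr))
    hop = frame_len - int(round(overlap_s * sr))
    if frame_len < 1 or hop < 1:
        raise ValueError("frame length and hop must be at least one sample")
    x = rec.samples
    if x.size < frame_len:
        raise ValueError(
            f"signal of {x.size} samples is shorter than one frame ({frame_len})"
        )
    frames = np.lib.stride_tricks.sliding_window_view(x, frame_len)[::hop].copy()
    return FrameMatrix(
        frames=frames,
        frame_len_samples=frame_len,
        hop_samples=hop,
        sample_rate_hz=sr,
    )


def hamming_window(n: int) -> np.ndarray:
    """w(k) = 0.54 - 0.46 cos(2*pi*k / (n-1)), 0 <= k <= n-1."""
    return np.hamming(n)


def apply_hamming(fm: FrameMatrix) -> FrameMatrix:
    if fm.windowed:
        raise ValueError("frames are already windowed")
    w = hamming_window(fm.frame_len_samples)
    return replace(fm, frames=fm.frames * w, windowed=True)
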