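"""WAV audio and segment-label file I/O.

Audio is carried as an :class:`AudioRecording` with samples scaled to the
nominal range [-1, 1].  Segment annotations use WaveSurfer-style label files:
one ``start<TAB>end<TAB>label`` line per segment, times in seconds.  Segments
are half-open intervals ``[start, end)`` so that abutting segments do not
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "LABEL_VOCABULARY",
    "AudioRecording",
    "Segment",
    "LabelTrack",
    "LabelFileError",
    "read_wav",
    "write_wav",
    "to_mono",
    "read_labels",
    "write_labels",
    "frames_to_time",
]

#: Annotation alphabet: cry expirations (typical / faint / babbling), audible
#: and silent inspirations, adult speech, machine beeps, other noise and
#: background silence.
LABEL_VOCABULARY = (
    "EXP", "INSV", "INS", "EXPN", "EXP2", "INS2", "SP", "BIP", "NOR", "BKG",
)

_TIME_TOL = 1e-9


class LabelFileError(ValueError):
    """Raised for malformed or inconsistent label files."""


@dataclass
class AudioRecording:
    """A sampled waveform.

    ``samples`` has shape ``(n,)`` for mono or ``(n, 2)`` for stereo, with
    amplitudes in the nominal range [-1, 1].
    """

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size == 0:
            raise ValueError("recording is empty")
        if self.samples.ndim not in (1, 2):
            raise ValueError("samples must be 1-D (mono) or 2-D (stereo)")
        if self.samples.ndim == 2 and self.samples.shape[1] not in (1, 2):
            raise ValueError("only 1- or 2-channel audio is supported")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass(frozen=True)
class Segment:
    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(
                f"segment must have start < end, got [{self.start_s}, {self.end_s})"
            )
        if self.label not in LABEL_VOCABULARY:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class LabelTrack:
    """An ordered, overlap-free sequence of labeled time segments."""

    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (s.start_s, s.end_s))
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start_s < a.end_s - _TIME_TOL:
                raise LabelFileError(
                    f"overlapping segments: [{a.start_s}, {a.end_s}) {a.label} and "
                    f"[{b.start_s}, {b.end_s}) {b.label}"
                )

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def label_at(self, t_s: float, default: str | None = None) -> str | None:
        """Label of the segment containing time ``t_s`` (half-open intervals)."""
        for seg in self.segments:
            if seg.start_s <= t_s < seg.end_s:
                return seg.label
        return default


def _scale_to_float(data: np.ndarray) -> np.ndarray:
    if data.dtype == np.int16:
        return data / 32768.0
    if data.dtype == np.int32:
        return data / 2147483648.0
    if data.dtype == np.uint8:
        return (data.astype(np.float64) - 128.0) / 128.0
    if np.issubdtype(data.dtype, np.floating):
        return data.astype(np.float64)
    raise LabelFileError(f"unsupported WAV sample format {data.dtype}")


def read_wav(path: str | Path) -> AudioRecording:
    """Read a PCM WAV file, scaling samples to [-1, 1]."""
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:  # compressed / non-PCM
        raise LabelFileError(f"cannot read {path}: {exc}") from exc
    return AudioRecording(samples=_scale_to_float(data), sample_rate_hz=int(rate))


def write_wav(rec: AudioRecording, path: str | Path) -> None:
    """Write 16-bit PCM. Amplitudes outside [-1, 1] are clipped."""
    scaled = np.clip(np.round(rec.samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), rec.sample_rate_hz, scaled)


def to_mono(rec: AudioRecording) -> AudioRecording:
    """Average the two channels of a stereo recording; mono passes through."""
    if rec.n_channels == 1:
        return rec
    return AudioRecording(rec.samples.mean(axis=1), rec.sample_rate_hz)


def read_labels(path: str | Path) -> LabelTrack:
    segments = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise LabelFileError(f"{path}:{lineno}: expected 'start end label', got {line!r}")
            try:
                start_s, end_s = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise LabelFileError(f"{path}:{lineno}: bad time field: {exc}") from exc
            try:
                segments.append(Segment(start_s, end_s, parts[2]))
            except ValueError as exc:
                raise LabelFileError(f"{path}:{lineno}: {exc}") from exc
    return LabelTrack(segments)


def write_labels(track: LabelTrack, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for seg in track:
            fh.write(f"{seg.start_s:.6f}\t{seg.end_s:.6f}\t{seg.label}\n")


def frames_to_time(
    frame_index: int, frame_len_s: float, hop_s: float
) -> tuple[float, float]:
    """Span in seconds of a 1-based analysis frame.

    Frame ``i`` starts at ``(i - 1) * hop`` and covers one frame length.
    """
    if frame_index < 1:
        raise ValueError("frame_index is 1-based and must be >= 1")
    if frame_len_s <= 0 or not 0 < hop_s <= frame_len_s:
        raise ValueError("need frame_len_s > 0 and 0 < hop_s <= frame_len_s")
    start_s = (frame_index - 1) * hop_s
    return start_s, start_s + frame_len_s


def frame_run_to_span(
    start_frame: int, end_frame: int, n_frames: int,
    frame_len_s: float, hop_s: float,
) -> tuple[float, float]:
    """Time span of a run of frames (1-based, inclusive) on the frame grid.

    Boundaries between abutting runs sit midway between the adjacent frame
    centers, so sampling a track at frame centers recovers the run labels
    exactly; the first run starts at 0 and the last ends with the last frame.
    """
    if not 1 <= start_frame <= end_frame <= n_frames:
        raise ValueError("need 1 <= start_frame <= end_frame <= n_frames")
    half = (frame_len_s - hop_s) / 2.0
    start_s = 0.0 if start_frame == 1 else (start_frame - 1) * hop_s + half
    if end_frame == n_frames:
        end_s = (n_frames - 1) * hop_s + frame_len_s
    else:
        end_s = end_frame * hop_s + half
    return start_s, end_s
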