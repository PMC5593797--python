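"""Seeded synthesis of cry scenes with exact ground-truth labels.

The clinical recordings this system targets cannot be redistributed, so every
stage is exercised on synthetic scenes instead.  Events are generated by a
simple source–filter scheme: expiratory cries are harmonic sources with a
programmable F0 contour (default 250–700 Hz), pitch jitter, amplitude shimmer
and raised-cosine onset/offset envelopes; vocalized inspirations are short
harmonic bursts in a lower, distinct F0 band; adult speech is a 100–300 Hz
harmonic with syllabic amplitude modulation; machine beeps are constant
frequency tones; background is low-level white noise and "other" activity is
gated broadband noise.  Identical (spec, seed) pairs render bit-identical
audio.

These scenes reproduce the class structure the segmenter exploits (harmonic
voicing, distinct F0 bands, intensity contrast against background); they do
not attempt perceptual realism, reverberation or overlapping sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, lfilter

from .io_formats import AudioRecording, LabelTrack, Segment, write_labels, write_wav

__all__ = [
    "Event",
    "SceneSpec",
    "synth_event",
    "render_scene",
    "random_scene",
    "make_training_corpus",
]

EVENT_CLASSES = ("EXP", "INSV", "SP", "BIP", "BKG", "NOR")

DEFAULT_SAMPLE_RATE = 16000
DEFAULT_NOISE_FLOOR = 0.002


@dataclass(frozen=True)
class Event:
    """One scene event; ``label`` must be an annotation label."""

    label: str
    duration_s: float
    f0_start_hz: float = 0.0
    f0_end_hz: float = 0.0
    amplitude: float = 0.3
    jitter: float = 0.01     # fractional F0 perturbation
    shimmer: float = 0.05    # fractional amplitude perturbation

    def __post_init__(self) -> None:
        if self.label not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.label!r}")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        for f in (self.f0_start_hz, self.f0_end_hz):
            if f and not 50.0 <= f <= 1500.0:
                raise ValueError(f"f0 {f} Hz outside the plausible [50, 1500] band")


@dataclass
class SceneSpec:
    events: list[Event]
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE
    seed: int = 0
    noise_floor: float = DEFAULT_NOISE_FLOOR


def _smooth_noise(n: int, sr: int, rng: np.random.Generator, step_ms: float = 10.0) -> np.ndarray:
    """Slowly varying zero-mean noise in [-1, 1] (linear ramps between knots)."""
    step = max(1, int(sr * step_ms / 1000.0))
    knots = rng.uniform(-1.0, 1.0, size=n // step + 2)
    t = np.arange(n) / step
    return np.interp(t, np.arange(knots.size), knots)


def _envelope(n: int, sr: int, edge_s: float = 0.04) -> np.ndarray:
    edge = min(n // 2, max(1, int(edge_s * sr)))
    env = np.ones(n)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(edge) / edge))
    env[:edge] = ramp
    env[-edge:] = ramp[::-1]
    return env


def _harmonic(
    n: int,
    sr: int,
    f0_start: float,
    f0_end: float,
    amplitude: float,
    jitter: float,
    shimmer: float,
    rng: np.random.Generator,
    tilt: float = 1.0,
) -> np.ndarray:
    """Harmonic source with linear F0 contour and 1/h^tilt spectral rolloff."""
    f0 = np.linspace(f0_start, f0_end, n)
    if jitter:
        f0 = f0 * (1.0 + jitter * _smooth_noise(n, sr, rng))
    phase = 2.0 * np.pi * np.cumsum(f0) / sr
    f0_max = float(f0.max())
    n_harm = max(1, int(0.45 * sr / f0_max))
    x = np.zeros(n)
    for h in range(1, n_harm + 1):
        x += np.sin(h * phase) / h**tilt
    x *= amplitude / np.max(np.abs(x))
    if shimmer:
        x *= 1.0 + shimmer * _smooth_noise(n, sr, rng)
    return x * _envelope(n, sr)


def synth_event(event: Event, sample_rate_hz: int, rng: np.random.Generator) -> np.ndarray:
    """Render one event to samples."""
    sr = sample_rate_hz
    n = int(round(event.duration_s * sr))
    if event.label in ("EXP", "INSV", "SP"):
        x = _harmonic(
            n, sr, event.f0_start_hz, event.f0_end_hz,
            event.amplitude, event.jitter, event.shimmer, rng,
        )
        if event.label == "SP":  # syllabic amplitude modulation, ~4 syllables/s
            t = np.arange(n) / sr
            x *= 0.2 + 0.8 * 0.5 * (1.0 + np.sin(2.0 * np.pi * 4.0 * t))
        return x
    if event.label == "BIP":
        t = np.arange(n) / sr
        return event.amplitude * np.sin(2.0 * np.pi * event.f0_start_hz * t) * _envelope(n, sr)
    if event.label == "BKG":
        return event.amplitude * rng.standard_normal(n)
    if event.label == "NOR":
        noise = rng.standard_normal(n)
        b, a = butter(4, [300.0 / (sr / 2), 4000.0 / (sr / 2)], btype="band")
        noise = lfilter(b, a, noise)
        gate = (_smooth_noise(n, sr, rng, step_ms=80.0) > -0.3).astype(float)
        x = event.amplitude * noise * gate
        return x * _envelope(n, sr)
    raise ValueError(f"unknown event class {event.label!r}")


def render_scene(spec: SceneSpec) -> tuple[AudioRecording, LabelTrack]:
    """Concatenate the events of a scene over a common noise floor."""
    rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate_hz
    pieces, segments = [], []
    t = 0.0
    for ev in spec.events:
        x = synth_event(ev, sr, rng)
        pieces.append(x)
        segments.append(Segment(t, t + x.size / sr, ev.label))
        t += x.size / sr
    samples = np.concatenate(pieces)
    if spec.noise_floor:
        samples = samples + spec.noise_floor * rng.standard_normal(samples.size)
    samples = np.clip(samples, -1.0, 1.0)
    return AudioRecording(samples, sr), LabelTrack(segments)


def random_scene(seed: int, sample_rate_hz: int = DEFAULT_SAMPLE_RATE) -> SceneSpec:
    """A plausible scene: cry cycles (expiration + vocalized inspiration with
    pauses) bracketed by background, with optional speech / beep / noise."""
    rng = np.random.default_rng(seed)
    events = [Event("BKG", rng.uniform(0.8, 1.2), amplitude=0.003)]
    for _ in range(int(rng.integers(2, 4))):
        f0a = rng.uniform(300.0, 500.0)
        events.append(Event("EXP", rng.uniform(1.0, 2.0), f0a,
                            f0a + rng.uniform(-50.0, 120.0), amplitude=0.35))
        if rng.uniform() < 0.8:
            f0i = rng.uniform(170.0, 230.0)
            events.append(Event("INSV", rng.uniform(0.25, 0.5), f0i,
                                f0i + rng.uniform(-15.0, 15.0), amplitude=0.2))
        events.append(Event("BKG", rng.uniform(0.3, 0.6), amplitude=0.003))
    if rng.uniform() < 0.5:
        f0s = rng.uniform(110.0, 160.0)
        events.append(Event("SP", rng.uniform(0.8, 1.2), f0s, f0s + 30.0,
                            amplitude=0.15))
    if rng.uniform() < 0.3:
        events.append(Event("BIP", 0.4, 1000.0, 1000.0, amplitude=0.1, jitter=0.0))
    if rng.uniform() < 0.4:
        events.append(Event("NOR", rng.uniform(0.4, 0.8), amplitude=0.12))
    events.append(Event("BKG", rng.uniform(0.5, 0.9), amplitude=0.003))
    return SceneSpec(events=events, sample_rate_hz=sample_rate_hz, seed=seed)


def make_training_corpus(
    n_scenes: int,
    seed: int,
    outdir: str | Path,
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE,
) -> list[tuple[Path, Path]]:
    """Write ``n_scenes`` WAV + label pairs; returns the file path pairs."""
    if n_scenes < 1:
        raise ValueError("need at least one scene")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pairs = []
    for i in range(n_scenes):
        spec = random_scene(seed=(seed * 9973 + i) % (2**31 - 1),
                            sample_rate_hz=sample_rate_hz)
        rec, track = render_scene(spec)
        wav = outdir / f"scene_{i:03d}.wav"
        lab = outdir / f"scene_{i:03d}.lab"
        write_wav(rec, wav)
        write_labels(track, lab)
        pairs.append((wav, lab))
    return pairs
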