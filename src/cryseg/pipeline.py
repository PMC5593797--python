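"""End-to-end glue: feature recipes, bank training and whole-file runs.

The two supported configurations mirror the systems the segmenter was built
around: a GMM bank (40 mixtures per class) on FFT-based cepstra, and a
4-state HMM bank (40 Gaussians per class) on cepstra of the IMF3+IMF4+IMF5
recombination of a per-utterance empirical mode decomposition.  Both consume
the 39-dimensional static + delta + acceleration stack.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import emd as emd_mod
from .classifiers import ClassifierBank, classify_frames, train_gmm_bank, train_hmm_bank
from .config import RunConfig
from .evaluation import track_to_frame_labels
from .features import add_deltas, mfcc_fft
from .io_formats import (
    AudioRecording,
    LabelTrack,
    Segment,
    frame_run_to_span,
    read_labels,
    read_wav,
    to_mono,
)
from .postprocess import RelabelRules, refine
from .preprocess import apply_hamming, frame_signal, preemphasize

__all__ = [
    "extract_features",
    "labels_to_track",
    "frame_grid",
    "gather_training_data",
    "train_bank",
    "run_segment",
    "run_full",
    "find_corpus_pairs",
]


def frame_grid(rec: AudioRecording, config: RunConfig) -> int:
    """Number of analysis frames the configured framing yields for ``rec``."""
    mono = to_mono(rec)
    frame_len = int(round(config.frame_len_s * rec.sample_rate_hz))
    hop = frame_len - int(round(config.overlap_s * rec.sample_rate_hz))
    return (mono.n_samples - frame_len) // hop + 1


def extract_features(rec: AudioRecording, config: RunConfig) -> np.ndarray:
    """The 39-dim classifier features for one recording, per the recipe."""
    mono = to_mono(rec)
    emphasized = preemphasize(mono, config.preemphasis_alpha)
    if config.recipe == "emd-mfcc":
        decomp = emd_mod.decompose(
            emphasized.samples,
            n_imfs_min=max(config.imf_indices),
            sd_threshold=config.sd_threshold,
            max_sifts=config.max_sifts,
        )
        signal = AudioRecording(
            emd_mod.combine_imf345(decomp, config.imf_indices), mono.sample_rate_hz
        )
    else:
        signal = emphasized
    fm = apply_hamming(frame_signal(signal, config.frame_len_s, config.overlap_s))
    static = mfcc_fft(fm, config.n_filters, config.n_cepstra)
    return add_deltas(static, config.delta_window).values


def labels_to_track(
    frame_labels: np.ndarray, frame_len_s: float, hop_s: float
) -> LabelTrack:
    """Collapse per-frame labels into contiguous segments on the frame grid."""
    frame_labels = np.asarray(frame_labels)
    n = frame_labels.size
    segments = []
    start = 0
    for t in range(1, n + 1):
        if t == n or frame_labels[t] != frame_labels[start]:
            start_s, end_s = frame_run_to_span(start + 1, t, n, frame_len_s, hop_s)
            segments.append(Segment(start_s, end_s, str(frame_labels[start])))
            start = t
    return LabelTrack(segments)


def find_corpus_pairs(corpus_dir: str | Path) -> list[tuple[Path, Path]]:
    """WAV + label file pairs (same stem) under a corpus directory."""
    corpus_dir = Path(corpus_dir)
    pairs = []
    for wav in sorted(corpus_dir.glob("*.wav")):
        lab = wav.with_suffix(".lab")
        if lab.exists():
            pairs.append((wav, lab))
    if not pairs:
        raise FileNotFoundError(f"no WAV/label pairs found under {corpus_dir}")
    return pairs


def gather_training_data(
    pairs: list[tuple[Path, Path]], config: RunConfig
) -> dict[str, list[np.ndarray]]:
    """Per-class feature sequences from annotated recordings.

    Each recording contributes its contiguous same-class frame runs (ground
    truth collapsed onto the four system classes) as separate sequences.
    """
    by_class: dict[str, list[np.ndarray]] = {}
    for wav_path, lab_path in pairs:
        rec = read_wav(wav_path)
        track = read_labels(lab_path)
        X = extract_features(rec, config)
        ref = track_to_frame_labels(
            track, X.shape[0], config.frame_len_s, config.hop_s
        )
        start = 0
        for t in range(1, ref.size + 1):
            if t == ref.size or ref[t] != ref[start]:
                by_class.setdefault(str(ref[start]), []).append(X[start:t])
                start = t
    return by_class


def train_bank(pairs: list[tuple[Path, Path]], config: RunConfig) -> ClassifierBank:
    by_class = gather_training_data(pairs, config)
    if config.model_kind == "gmm":
        frames = {cls: np.vstack(seqs) for cls, seqs in by_class.items()}
        return train_gmm_bank(
            frames, config.n_components, seed=config.seed, recipe=config.recipe
        )
    seqs = {
        cls: [s for s in seq_list if s.shape[0] >= config.n_states]
        for cls, seq_list in by_class.items()
    }
    return train_hmm_bank(
        seqs, config.n_states, config.n_mix, seed=config.seed, recipe=config.recipe
    )


def run_segment(
    rec: AudioRecording, bank: ClassifierBank, config: RunConfig
) -> tuple[np.ndarray, LabelTrack]:
    """Initial classification: per-frame labels and their segment track."""
    X = extract_features(rec, config)
    labels = classify_frames(
        bank, X, smooth_window=config.smooth_window,
        switch_penalty=config.switch_penalty,
    )
    return labels, labels_to_track(labels, config.frame_len_s, config.hop_s)


def run_full(
    rec: AudioRecording, bank: ClassifierBank, config: RunConfig,
    return_details: bool = False,
):
    """Initial classification followed by post-processing refinement."""
    labels, _ = run_segment(rec, bank, config)
    return refine(
        labels, rec,
        frame_len_s=config.frame_len_s,
        overlap_s=config.overlap_s,
        f0_min_hz=config.f0_min_hz,
        f0_max_hz=config.f0_max_hz,
        voicing_threshold=config.voicing_threshold,
        silence_span_ms=config.silence_span_ms,
        rules=RelabelRules(config.exp_band, config.ins_band),
        linear_energy=config.linear_energy,
        return_details=return_details,
    )
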