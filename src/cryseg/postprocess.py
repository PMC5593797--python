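"""Label refinement and boundary sharpening.

The initial frame classification is corrected with evidence from three cheap
side features — frame intensity (dB), zero-crossing count and the
fundamental-frequency track:

1.  Dynamic thresholds ZC_BKG and INT_BKG are estimated from 250 ms of
    background silence (Rabiner–Sambur style endpoint detection):
    ZC_BKG = mean(ZCR_sil) + 2 std(ZCR_sil);  Imean = mean(INT_sil);
    Imax = max(INT_sig);  I1 = 0.03 (Imax − Imean) + Imean;  I2 = 4 Imean;
    ITL = min(I1, I2);  INT_BKG = 5 ITL.
2.  Each frame gets a voicing index (1 if an F0 estimate exists, else 0);
    the last frame of every voicing run and every local intensity minimum are
    marked "2", and the marks split the frame axis into intervals.
3.  Each interval is re-indexed active (1) when its mean intensity or mean
    ZCR reaches the thresholds, else inactive (0); the index is concatenated
    with the initial class into a composite label (e.g. "EXP1").
4.  Runs of equal composite labels become candidate utterances: inactive runs
    fall back to background, active EXP/INS runs keep their class, and active
    runs of the other classes are relabeled by their mean F0 against
    configurable expiration / inspiration bands.

Frame indices in the public interval and table structures are 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import F0Track, f0_autocorr, intensity as frame_intensity, zcr as frame_zcr
from .io_formats import AudioRecording, LabelTrack, Segment, frame_run_to_span, to_mono
from .preprocess import DEFAULT_FRAME_LEN_S, DEFAULT_OVERLAP_S, frame_signal

__all__ = [
    "ThresholdSet",
    "RelabelRules",
    "compute_thresholds",
    "voicing_index",
    "mark_transitions",
    "mark_intensity_minima",
    "combine_indices",
    "build_intervals",
    "classify_intervals",
    "merge_with_initial",
    "finalize_labels",
    "refine",
]

DEFAULT_SILENCE_SPAN_MS = 250.0


@dataclass
class ThresholdSet:
    """Dynamic background thresholds and their intermediates."""

    zc_bkg: float          # crossings / frame
    int_bkg: float         # dB
    imean: float
    imax: float
    i1: float
    i2: float
    itl: float
    source: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    # frame indices (0-based) that supplied the silence statistics


@dataclass
class RelabelRules:
    """F0-based final relabeling rules.

    Active runs of the non-cry classes are relabeled by their mean F0 against
    the expiration and inspiration bands (Hz); the expiration band takes
    precedence where they overlap.  Speech-range fundamentals (roughly
    100–300 Hz) without cry-level intensity never reach this rule: their
    intervals fail the activity test and fall to background.

    Two guards keep the rule from firing on non-phonated material.  A run is
    only treated as voiced when at least ``min_voiced_fraction`` of its frames
    carry an F0 estimate (the mean F0 of a few spuriously voiced frames in a
    noise burst is not a fundamental of the run).  And a run whose F0 spans
    less than ``beep_f0_span_hz`` is beep-like — machine beeps hold a constant
    fundamental, unlike the jittery contour of phonation — and keeps its
    composite class.
    """

    exp_band: tuple[float, float] = (250.0, 1000.0)
    ins_band: tuple[float, float] = (100.0, 800.0)
    min_voiced_fraction: float = 0.5
    beep_f0_span_hz: float = 1.0


def _silence_frames(
    intensity_db: np.ndarray, initial_labels: np.ndarray, n_sil: int
) -> np.ndarray:
    bkg = np.flatnonzero(initial_labels == "BKG")
    if bkg.size >= 1:
        return bkg[:n_sil]
    # no background was classified: fall back to the quietest window
    if intensity_db.size <= n_sil:
        return np.arange(intensity_db.size)
    means = np.convolve(intensity_db, np.ones(n_sil) / n_sil, mode="valid")
    start = int(np.argmin(means))
    return np.arange(start, start + n_sil)


def compute_thresholds(
    intensity_db: np.ndarray,
    zcr_counts: np.ndarray,
    initial_labels: np.ndarray,
    hop_s: float = DEFAULT_FRAME_LEN_S - DEFAULT_OVERLAP_S,
    silence_span_ms: float = DEFAULT_SILENCE_SPAN_MS,
    linear_energy: bool = True,
) -> ThresholdSet:
    """Estimate ZC_BKG and INT_BKG from the initially classified silence.

    The silence statistics come from the earliest ``silence_span_ms`` of
    frames labeled BKG by the initial classification (fallback: the
    minimum-intensity window of the same length).  By default the printed
    multiplicative forms are applied directly to the dB-scale intensities;
    ``linear_energy=True`` applies them on linear energy instead and converts
    the resulting threshold back to dB.
    """
    intensity_db = np.asarray(intensity_db, dtype=np.float64)
    zcr_counts = np.asarray(zcr_counts, dtype=np.float64)
    initial_labels = np.asarray(initial_labels)
    if intensity_db.size == 0:
        raise ValueError("need at least one frame")
    n_sil = max(1, int(round(silence_span_ms / 1000.0 / hop_s)))
    if intensity_db.size < n_sil:
        warnings.warn(
            f"signal has {intensity_db.size} frames, shorter than the "
            f"{silence_span_ms:.0f} ms silence span; using all frames"
        )
        n_sil = intensity_db.size
    sil = _silence_frames(intensity_db, initial_labels, n_sil)

    zc_sil = zcr_counts[sil]
    zc_bkg = float(zc_sil.mean() + 2.0 * zc_sil.std())

    int_sil = intensity_db[sil]
    int_sig = intensity_db
    if linear_energy:
        int_sil = 10.0 ** (int_sil / 10.0)
        int_sig = 10.0 ** (int_sig / 10.0)
    imean = float(int_sil.mean())
    imax = float(int_sig.max())
    i1 = 0.03 * (imax - imean) + imean
    i2 = 4.0 * imean
    itl = min(i1, i2)
    int_bkg = 5.0 * itl
    if linear_energy:
        imean, imax, i1, i2, itl, int_bkg = (
            10.0 * np.log10(max(v, 1e-30)) for v in (imean, imax, i1, i2, itl, int_bkg)
        )
    return ThresholdSet(zc_bkg, int_bkg, imean, imax, i1, i2, itl, source=sil)


def voicing_index(f0: F0Track) -> np.ndarray:
    """1 where an F0 estimate exists, 0 elsewhere."""
    if f0.f0_hz.size == 0:
        raise ValueError("empty F0 track")
    return f0.voiced.astype(int)


def mark_transitions(voicing: np.ndarray) -> np.ndarray:
    """Mark the last frame of every voicing run (boolean array).

    Frame t is marked when voicing changes between t and t+1; the final frame
    is never marked here (it always terminates the last interval anyway).
    """
    voicing = np.asarray(voicing)
    if voicing.size == 0:
        raise ValueError("empty voicing index")
    marks = np.zeros(voicing.size, dtype=bool)
    marks[:-1] = voicing[:-1] != voicing[1:]
    return marks


def mark_intensity_minima(
    intensity_db: np.ndarray, median_smooth: bool = False
) -> np.ndarray:
    """Mark local minima of the intensity contour (boolean array).

    Interior frame t is a minimum when I[t] < I[t-1] and I[t] <= I[t+1]; the
    first frame is marked when the contour rises away from it. Optional
    3-frame median smoothing can be applied before detection.
    """
    x = np.asarray(intensity_db, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 frames to detect minima")
    if median_smooth:
        from scipy.signal import medfilt

        x = medfilt(x, 3)
    marks = np.zeros(x.size, dtype=bool)
    marks[1:-1] = (x[1:-1] < x[:-2]) & (x[1:-1] <= x[2:])
    marks[0] = x[0] < x[1]
    return marks


def combine_indices(
    voicing: np.ndarray, transitions: np.ndarray, minima: np.ndarray
) -> np.ndarray:
    """Merge voicing with the two mark channels into a {0,1,2} index.

    A frame combines to 2 when it carries a transition or minima mark, or is
    the final frame; otherwise it keeps its voicing index.
    """
    voicing = np.asarray(voicing)
    if not (voicing.size == len(transitions) == len(minima)):
        raise ValueError("voicing, transitions and minima must share length")
    combined = voicing.astype(int).copy()
    combined[np.asarray(transitions) | np.asarray(minima)] = 2
    combined[-1] = 2
    return combined


def build_intervals(combined: np.ndarray) -> list[tuple[int, int]]:
    """Intervals (1-based, inclusive) delimited by the combined "2" marks.

    Every marked frame after the first ends an interval; a mark on frame 1
    ends the singleton [1, 1] only when frame 2 is marked as well — otherwise
    it opens the first interval (a start-of-signal minimum is a start marker,
    not a boundary to cut at).
    """
    combined = np.asarray(combined)
    n = combined.size
    if n == 0:
        raise ValueError("empty combined index")
    if combined[-1] != 2:
        raise ValueError("the final frame must carry the combined index 2")
    marked = np.flatnonzero(combined == 2) + 1  # 1-based
    ends = []
    for t in marked:
        if t == 1 and not (n >= 2 and combined[1] == 2):
            continue
        ends.append(int(t))
    intervals = []
    prev = 0
    for e in ends:
        intervals.append((prev + 1, e))
        prev = e
    return intervals


def classify_intervals(
    intervals: list[tuple[int, int]],
    intensity_db: np.ndarray,
    zcr_counts: np.ndarray,
    thresholds: ThresholdSet,
) -> list[int]:
    """Activity index per interval: 1 when the interval's mean intensity or
    mean ZCR reaches its background threshold, else 0."""
    out = []
    for start, end in intervals:
        if end < start:
            raise ValueError(f"empty interval ({start}, {end})")
        sl = slice(start - 1, end)
        mean_i = float(np.mean(intensity_db[sl]))
        mean_z = float(np.mean(zcr_counts[sl]))
        out.append(int(mean_i >= thresholds.int_bkg or mean_z >= thresholds.zc_bkg))
    return out


def merge_with_initial(
    initial_labels: np.ndarray,
    intervals: list[tuple[int, int]],
    new_index: list[int],
) -> np.ndarray:
    """Composite per-frame labels: initial class + interval activity index
    (e.g. "EXP1", "BKG0")."""
    initial_labels = np.asarray(initial_labels)
    covered = np.zeros(initial_labels.size, dtype=bool)
    composite = np.empty(initial_labels.size, dtype=object)
    for (start, end), idx in zip(intervals, new_index):
        for t in range(start - 1, end):
            composite[t] = f"{initial_labels[t]}{idx}"
            covered[t] = True
    if not covered.all():
        raise ValueError(
            f"frame {int(np.flatnonzero(~covered)[0]) + 1} lies outside every interval"
        )
    return composite.astype(str)


def _runs(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """Maximal runs of equal labels as (start, end, label), 1-based inclusive."""
    out = []
    start = 0
    for t in range(1, labels.size + 1):
        if t == labels.size or labels[t] != labels[start]:
            out.append((start + 1, t, str(labels[start])))
            start = t
    return out


def finalize_labels(
    composite: np.ndarray,
    intensity_db: np.ndarray,
    f0: F0Track,
    thresholds: ThresholdSet,
    rules: RelabelRules | None = None,
    frame_len_s: float = DEFAULT_FRAME_LEN_S,
    hop_s: float = DEFAULT_FRAME_LEN_S - DEFAULT_OVERLAP_S,
) -> LabelTrack:
    """Final decision on candidate utterances.

    Runs of equal composite labels become candidates carrying their mean
    intensity and F0 statistics.  Inactive runs (index 0) become background;
    active EXP/INS runs keep their class; other active runs are relabeled by
    mean F0 (expiration band first, then inspiration band, else NOR).
    Adjacent same-label runs merge, and boundaries convert to seconds on the
    frame grid.
    """
    rules = rules or RelabelRules()
    composite = np.asarray(composite)
    decisions: list[tuple[int, int, str]] = []
    for start, end, label in _runs(composite):
        base, idx = label[:-1], label[-1]
        if idx == "0":
            final = "BKG"
        elif base in ("EXP", "INS"):
            final = base
        else:
            sl = slice(start - 1, end)
            stats = f0.stats(sl)
            voiced_frac = float(np.mean(f0.voiced[sl]))
            if stats is None:
                warnings.warn(
                    f"active run {start}-{end} ({label}) has no voiced frame; "
                    "keeping its composite class"
                )
                final = base
            elif voiced_frac < rules.min_voiced_fraction:
                final = base
            elif stats[1] - stats[0] < rules.beep_f0_span_hz:
                final = base  # constant fundamental: beep-like, not phonation
            else:
                mean_f0 = stats[2]
                if rules.exp_band[0] <= mean_f0 <= rules.exp_band[1]:
                    final = "EXP"
                elif rules.ins_band[0] <= mean_f0 <= rules.ins_band[1]:
                    final = "INS"
                else:
                    final = "NOR"
        decisions.append((start, end, final))

    # merge adjacent equal labels
    merged: list[list] = []
    for start, end, label in decisions:
        if merged and merged[-1][2] == label:
            merged[-1][1] = end
        else:
            merged.append([start, end, label])

    n = composite.size
    segments = []
    for start, end, label in merged:
        start_s, end_s = frame_run_to_span(start, end, n, frame_len_s, hop_s)
        segments.append(Segment(start_s, end_s, label))
    return LabelTrack(segments)


def refine(
    initial_labels: np.ndarray,
    rec: AudioRecording,
    frame_len_s: float = DEFAULT_FRAME_LEN_S,
    overlap_s: float = DEFAULT_OVERLAP_S,
    f0_min_hz: float = 75.0,
    f0_max_hz: float = 1000.0,
    voicing_threshold: float = 0.45,
    silence_span_ms: float = DEFAULT_SILENCE_SPAN_MS,
    rules: RelabelRules | None = None,
    linear_energy: bool = True,
    return_details: bool = False,
):
    """Run the full refinement pipeline on one recording.

    ``initial_labels`` holds one class per analysis frame ({EXP, INS, BKG,
    NOR}) at the same framing as used here.  Returns the refined
    :class:`LabelTrack`; with ``return_details=True`` also a dict of the
    intermediate working state (thresholds, indices, intervals, composite).
    """
    mono = to_mono(rec)
    fm = frame_signal(mono, frame_len_s, overlap_s)
    initial_labels = np.asarray(initial_labels)
    if initial_labels.size != fm.n_frames:
        raise ValueError(
            f"{initial_labels.size} initial labels for {fm.n_frames} frames"
        )
    intensity_db = frame_intensity(fm)
    zcr_counts = frame_zcr(fm)
    f0 = f0_autocorr(fm, f0_min_hz, f0_max_hz, voicing_threshold)

    thresholds = compute_thresholds(
        intensity_db, zcr_counts, initial_labels,
        hop_s=fm.hop_s, silence_span_ms=silence_span_ms,
        linear_energy=linear_energy,
    )
    voicing = voicing_index(f0)
    transitions = mark_transitions(voicing)
    minima = mark_intensity_minima(intensity_db)
    combined = combine_indices(voicing, transitions, minima)
    intervals = build_intervals(combined)
    new_index = classify_intervals(intervals, intensity_db, zcr_counts, thresholds)
    composite = merge_with_initial(initial_labels, intervals, new_index)
    track = finalize_labels(
        composite, intensity_db, f0, thresholds, rules,
        frame_len_s=fm.frame_len_s, hop_s=fm.hop_s,
    )
    if not return_details:
        return track
    return track, {
        "thresholds": thresholds,
        "voicing": voicing,
        "transitions": transitions,
        "minima": minima,
        "combined": combined,
        "intervals": intervals,
        "new_index": new_index,
        "composite": composite,
        "intensity": intensity_db,
        "zcr": zcr_counts,
        "f0": f0,
    }
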