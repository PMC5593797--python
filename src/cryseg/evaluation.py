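"""Frame-level scoring and cross-validation splitting.

Performance is measured one class at a time by comparing each hypothesized
frame label to the reference annotation: TP/FP/TN/FN counts, the derived
rates TPR = TP/(TP+FN), FPR = FP/(FP+TN), FNR = FN/(TP+FN) (in percent) and
an overall frame accuracy.  The ten annotation labels collapse onto the four
system classes for scoring.  Cross-validation folds are assigned by
recording, never by frame, to avoid leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import LabelTrack

__all__ = [
    "SCORING_CLASSES",
    "ConfusionCounts",
    "collapse_label",
    "frame_confusion",
    "rates",
    "overall_accuracy",
    "evaluation_report",
    "kfold_split",
    "track_to_frame_labels",
]

SCORING_CLASSES = ("EXP", "INS", "BKG", "NOR")

#: Annotation label -> system class.  EXP keeps its class, vocalized
#: inspirations map to INS, background to BKG; everything else (silent
#: inspiration, faint cries, babbling, speech, beeps, noise) is "other".
_COLLAPSE = {"EXP": "EXP", "INSV": "INS", "BKG": "BKG"}


def collapse_label(label: str) -> str:
    return _COLLAPSE.get(label, "NOR")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def frame_confusion(
    reference: np.ndarray, hypothesis: np.ndarray, cls: str
) -> ConfusionCounts:
    """One-vs-rest frame counts for ``cls``."""
    reference = np.asarray(reference)
    hypothesis = np.asarray(hypothesis)
    if reference.shape != hypothesis.shape:
        raise ValueError(
            f"reference has {reference.size} frames, hypothesis {hypothesis.size}"
        )
    ref = reference == cls
    hyp = hypothesis == cls
    return ConfusionCounts(
        tp=int(np.sum(ref & hyp)),
        fp=int(np.sum(~ref & hyp)),
        tn=int(np.sum(~ref & ~hyp)),
        fn=int(np.sum(ref & ~hyp)),
    )


def rates(c: ConfusionCounts) -> dict[str, float | None]:
    """TPR / FPR / FNR in percent; None where the denominator is zero."""
    pos = c.tp + c.fn
    neg = c.fp + c.tn
    return {
        "TPR": 100.0 * c.tp / pos if pos else None,
        "FPR": 100.0 * c.fp / neg if neg else None,
        "FNR": 100.0 * c.fn / pos if pos else None,
    }


def overall_accuracy(reference: np.ndarray, hypothesis: np.ndarray) -> float:
    """Correctly labeled frames / total frames, in percent."""
    reference = np.asarray(reference)
    hypothesis = np.asarray(hypothesis)
    if reference.shape != hypothesis.shape:
        raise ValueError("reference and hypothesis must have equal length")
    return 100.0 * float(np.mean(reference == hypothesis))


def evaluation_report(
    reference: np.ndarray, hypothesis: np.ndarray
) -> dict:
    """Per-class rates plus overall accuracy as one nested dict."""
    report: dict = {"classes": {}, "accuracy": overall_accuracy(reference, hypothesis)}
    for cls in SCORING_CLASSES:
        c = frame_confusion(reference, hypothesis, cls)
        report["classes"][cls] = {
            "TP": c.tp, "FP": c.fp, "TN": c.tn, "FN": c.fn, **rates(c),
        }
    return report


def kfold_split(
    recording_ids: list, k: int, seed: int = 0
) -> list[tuple[list, list]]:
    """Deterministic k-fold partition of recording ids.

    Returns ``k`` (train, test) pairs; test folds are pairwise disjoint,
    cover every id, and differ in size by at most one.
    """
    ids = list(recording_ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} recordings")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds = [list(np.asarray(ids, dtype=object)[chunk])
             for chunk in np.array_split(order, k)]
    out = []
    for i in range(k):
        test = folds[i]
        train = [x for j, fold in enumerate(folds) if j != i for x in fold]
        out.append((train, test))
    return out


def track_to_frame_labels(
    track: LabelTrack,
    n_frames: int,
    frame_len_s: float,
    hop_s: float,
    collapse: bool = True,
    default: str = "BKG",
) -> np.ndarray:
    """Sample a label track on the analysis frame grid.

    Each frame takes the label of the segment containing its center; frames
    outside every segment take ``default``.  ``collapse`` maps the annotation
    vocabulary onto the four system classes and is meant for ground-truth
    tracks only: system-output tracks already use the class vocabulary, where
    "INS" denotes the vocalized inspiration class, not the silent-pause
    annotation label of the same name — collapsing them would corrupt it.
    """
    labels = []
    for i in range(n_frames):
        center = i * hop_s + frame_len_s / 2.0
        lbl = track.label_at(center, default=default)
        labels.append(collapse_label(lbl) if collapse else lbl)
    return np.array(labels)
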