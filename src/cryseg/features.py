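"""Per-frame acoustic features.

Two feature groups are computed:

* the 39-dimensional classifier input — 12 mel-frequency cepstra plus a
  log-energy term, with delta and acceleration coefficients appended;
* the post-processing side channel — frame intensity in dB, zero-crossing
  count, and an autocorrelation fundamental-frequency track with per-utterance
  minimum / maximum / mean statistics.

Intensity, ZCR and F0 are meant to be computed on the raw (un-emphasized)
signal, since the post-processing thresholds emulate endpoint detection on
raw energy; the cepstra are computed on the pre-emphasized signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import rfft

from .preprocess import FrameMatrix, hamming_window

__all__ = [
    "FeatureMatrix",
    "F0Track",
    "intensity",
    "zcr",
    "f0_autocorr",
    "mel_scale",
    "mel_filterbank",
    "mfcc_fft",
    "add_deltas",
]

INTENSITY_FLOOR_EPS = 1e-10


@dataclass
class FeatureMatrix:
    """``n_frames x D`` feature values with ordered dimension names."""

    values: np.ndarray
    dim_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[1] != len(self.dim_names):
            raise ValueError("dim_names length must equal feature dimensionality")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass
class F0Track:
    """Per-frame fundamental frequency; NaN marks unvoiced frames."""

    f0_hz: np.ndarray

    def __post_init__(self) -> None:
        self.f0_hz = np.asarray(self.f0_hz, dtype=np.float64)

    @property
    def voiced(self) -> np.ndarray:
        return ~np.isnan(self.f0_hz)

    def stats(self, sl: slice | None = None) -> tuple[float, float, float] | None:
        """(min, max, mean) F0 over the voiced frames of ``sl``.

        Returns None when the span contains no voiced frame — the utterance
        statistics are undefined, not zero.
        """
        f0 = self.f0_hz if sl is None else self.f0_hz[sl]
        voiced = f0[~np.isnan(f0)]
        if voiced.size == 0:
            return None
        lo, hi = float(voiced.min()), float(voiced.max())
        # clamp: summation rounding must not push the mean outside [min, max]
        return lo, hi, float(min(max(voiced.mean(), lo), hi))


def intensity(fm: FrameMatrix, eps: float = INTENSITY_FLOOR_EPS) -> np.ndarray:
    """Sound intensity level per frame, in dB.

    I_t = 10*log10( sum_n s_t(n)^2 * w(n) + eps ) with w a Hamming window.
    Pass unwindowed frames; the window enters the sum here. The eps floor
    keeps silent frames finite.
    """
    w = hamming_window(fm.frame_len_samples)
    return 10.0 * np.log10(fm.frames**2 @ w + eps)


def zcr(fm: FrameMatrix) -> np.ndarray:
    """Zero crossings per frame; exact zeros count as positive."""
    if fm.windowed:
        raise ValueError("zcr needs unwindowed frames (the signal's own signs)")
    signs = np.where(fm.frames >= 0.0, 1, -1)
    return np.sum(signs[:, 1:] != signs[:, :-1], axis=1)


def f0_autocorr(
    fm: FrameMatrix,
    fmin_hz: float = 75.0,
    fmax_hz: float = 1000.0,
    voicing_threshold: float = 0.45,
) -> F0Track:
    """Autocorrelation pitch per frame.

    The normalized autocorrelation r(tau)/r(0) of the mean-removed frame is
    maximized over lags in [rate/fmax, rate/fmin]; a frame is voiced when the
    peak reaches ``voicing_threshold``, and then f0 = rate / tau*.
    """
    sr = fm.sample_rate_hz
    if not 0 < fmin_hz < fmax_hz < sr / 2:
        raise ValueError("need 0 < fmin_hz < fmax_hz < sample_rate/2")
    lag_lo = max(1, int(np.ceil(sr / fmax_hz)))
    lag_hi = min(fm.frame_len_samples - 1, int(np.floor(sr / fmin_hz)))
    if lag_hi < lag_lo:
        raise ValueError("frame too short for the requested pitch range")

    f0 = np.full(fm.n_frames, np.nan)
    n = fm.frame_len_samples
    for t in range(fm.n_frames):
        x = fm.frames[t] - fm.frames[t].mean()
        r0 = float(x @ x)
        if r0 <= 0.0:
            continue
        # full autocorrelation for positive lags in the search band
        r = np.correlate(x, x, mode="full")[n - 1 + lag_lo : n + lag_hi]
        k = int(np.argmax(r))
        if r[k] / r0 >= voicing_threshold:
            f0[t] = sr / (lag_lo + k)
    return F0Track(f0)


def mel_scale(f_hz):
    """Mel(f) = 2595 * log10(1 + f/700)."""
    f = np.asarray(f_hz, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    return 2595.0 * np.log10(1.0 + f / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(
    n_filters: int, n_fft: int, sample_rate_hz: int,
    fmin_hz: float = 0.0, fmax_hz: float | None = None,
) -> np.ndarray:
    """Triangular mel filters, shape ``(n_filters, n_fft//2 + 1)``."""
    if fmax_hz is None:
        fmax_hz = sample_rate_hz / 2.0
    mel_pts = np.linspace(mel_scale(fmin_hz), mel_scale(fmax_hz), n_filters + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bin_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate_hz)
    fbank = np.zeros((n_filters, bin_freqs.size))
    for j in range(n_filters):
        lo, ctr, hi = hz_pts[j], hz_pts[j + 1], hz_pts[j + 2]
        up = (bin_freqs - lo) / (ctr - lo)
        down = (hi - bin_freqs) / (hi - ctr)
        fbank[j] = np.maximum(0.0, np.minimum(up, down))
    return fbank


def mfcc_fft(
    fm: FrameMatrix,
    n_filters: int = 26,
    n_cepstra: int = 12,
    energy_eps: float = 1e-12,
) -> FeatureMatrix:
    """Mel-frequency cepstra of windowed frames.

    Pipeline: power spectrum (FFT size = next power of two >= frame length)
    -> triangular mel filterbank energies S_k -> natural log -> cosine
    transform c_n = sum_k log(S_k) cos(pi*n*(k-1/2)/M), n = 1..K. The frame
    log-energy is appended as a 13th static coefficient so that the stacked
    static + delta + acceleration vector has 39 dimensions.
    """
    if not fm.windowed:
        raise ValueError("mfcc_fft expects windowed frames")
    if n_cepstra > n_filters:
        raise ValueError("n_cepstra must not exceed n_filters")
    n_fft = 1 << (fm.frame_len_samples - 1).bit_length()
    power = np.abs(rfft(fm.frames, n=n_fft, axis=1)) ** 2
    fbank = mel_filterbank(n_filters, n_fft, fm.sample_rate_hz)
    log_s = np.log(np.maximum(power @ fbank.T, energy_eps))
    k = np.arange(1, n_filters + 1)
    n = np.arange(1, n_cepstra + 1)
    dct = np.cos(np.pi * np.outer(n, k - 0.5) / n_filters)  # (K, M)
    cep = log_s @ dct.T
    log_e = np.log(np.sum(fm.frames**2, axis=1) + energy_eps)
    values = np.column_stack([cep, log_e])
    names = [f"c{i}" for i in n] + ["logE"]
    return FeatureMatrix(values, names)


def add_deltas(fm: FeatureMatrix, window: int = 2) -> FeatureMatrix:
    """Append delta and acceleration coefficients (regression formula).

    Delta_t = sum_{th=1..W} th*(c_{t+th} - c_{t-th}) / (2*sum th^2), with
    edge frames replicated; acceleration is the delta of the deltas. Output
    dimensionality is three times the input.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if fm.n_frames < 2 * window + 1:
        raise ValueError(
            f"need at least {2 * window + 1} frames for delta window {window}"
        )

    def _delta(x: np.ndarray) -> np.ndarray:
        padded = np.pad(x, ((window, window), (0, 0)), mode="edge")
        denom = 2.0 * sum(th * th for th in range(1, window + 1))
        out = np.zeros_like(x)
        for th in range(1, window + 1):
            out += th * (padded[window + th : window + th + x.shape[0]]
                         - padded[window - th : window - th + x.shape[0]])
        return out / denom

    d = _delta(fm.values)
    dd = _delta(d)
    names = (
        list(fm.dim_names)
        + [f"d_{n}" for n in fm.dim_names]
        + [f"dd_{n}" for n in fm.dim_names]
    )
    return FeatureMatrix(np.column_stack([fm.values, d, dd]), names)
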