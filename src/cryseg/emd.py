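"""Empirical mode decomposition by sifting.

A signal is decomposed into intrinsic mode functions (IMFs) and a residue.
One sifting pass interpolates the local maxima and minima with cubic splines
(mirror-extended at the boundaries) to form upper and lower envelopes u(t),
l(t), and subtracts the envelope midline m(t) = (u + l)/2 from the signal.
Sifting repeats until the candidate satisfies the two IMF criteria — the
numbers of extrema and zero crossings are equal or differ by one, and the
envelope mean is (near) zero — or until the Huang standard-deviation statistic
SD = sum((h_prev - h)^2) / sum(h_prev^2) falls below a threshold.

The cepstral recipe downstream uses the pointwise sum IMF3 + IMF4 + IMF5 of a
per-utterance decomposition in place of the raw signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "EmdError",
    "InsufficientExtremaError",
    "IMFDecomposition",
    "sift_once",
    "extract_imf",
    "decompose",
    "combine_imf345",
]

DEFAULT_SD_THRESHOLD = 0.2
DEFAULT_MAX_SIFTS = 100


class EmdError(ValueError):
    pass


class InsufficientExtremaError(EmdError):
    """Fewer than two maxima or two minima: the signal cannot be sifted."""


@dataclass
class IMFDecomposition:
    imfs: list[np.ndarray]
    residue: np.ndarray
    sift_counts: list[int] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateau midpoints count once)."""
    dx = np.diff(x)
    # collapse zero slopes onto the preceding sign so plateaus give one extremum
    sign = np.sign(dx)
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    flips = np.diff(sign)
    maxima = np.where(flips < 0)[0] + 1
    minima = np.where(flips > 0)[0] + 1
    return maxima, minima


def _count_zero_crossings(x: np.ndarray) -> int:
    s = np.where(x >= 0.0, 1, -1)
    return int(np.sum(s[1:] != s[:-1]))


def _envelope(x: np.ndarray, idx: np.ndarray, n_mirror: int = 2) -> np.ndarray:
    """Cubic-spline envelope through the extrema at ``idx``, mirror-extended."""
    n = x.size
    k = min(n_mirror, idx.size)
    left_t = -idx[:k][::-1]
    left_v = x[idx[:k][::-1]]
    right_t = 2 * (n - 1) - idx[-k:][::-1]
    right_v = x[idx[-k:][::-1]]
    t = np.concatenate([left_t, idx, right_t])
    v = np.concatenate([left_v, x[idx], right_v])
    t, keep = np.unique(t, return_index=True)
    return CubicSpline(t, v[keep])(np.arange(n))


def sift_once(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One sifting pass: returns (h, m) with h = x - m, m the envelope mean."""
    x = np.asarray(x, dtype=np.float64)
    maxima, minima = _local_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        raise InsufficientExtremaError(
            f"need >= 2 maxima and minima, found {maxima.size} and {minima.size}"
        )
    u = _envelope(x, maxima)
    l = _envelope(x, minima)
    m = 0.5 * (u + l)
    return x - m, m


def _is_imf(h: np.ndarray, boundary_slack: int = 1) -> bool:
    maxima, minima = _local_extrema(h)
    n_ext = maxima.size + minima.size
    n_zc = _count_zero_crossings(h)
    return abs(n_ext - n_zc) <= 1 + boundary_slack


def extract_imf(
    x: np.ndarray,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    max_sifts: int = DEFAULT_MAX_SIFTS,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Sift ``x`` down to one IMF.

    Returns ``(imf, residue_partial, n_sifts, converged)`` with
    ``residue_partial = x - imf``.
    """
    x = np.asarray(x, dtype=np.float64)
    h, _ = sift_once(x)
    n_sifts = 1
    converged = _is_imf(h, boundary_slack=0)
    sd = np.inf
    while not converged and n_sifts < max_sifts:
        try:
            h_new, _ = sift_once(h)
        except InsufficientExtremaError:
            break
        denom = float(h @ h)
        sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
        h = h_new
        n_sifts += 1
        # the count criterion is the binding condition; the SD statistic
        # alone stops long before the extrema/zero-crossing balance holds
        if _is_imf(h, boundary_slack=0) and (sd < sd_threshold or n_sifts >= 2):
            converged = True
    return h, x - h, n_sifts, converged


def decompose(
    x: np.ndarray,
    n_imfs_min: int = 0,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    max_sifts: int = DEFAULT_MAX_SIFTS,
    max_imfs: int = 16,
) -> IMFDecomposition:
    """Full decomposition: repeat IMF extraction on successive residues.

    Stops when the residue has too few extrema to sift (monotone or
    near-monotone) or ``max_imfs`` is reached. The telescoping construction
    makes ``sum(imfs) + residue`` reproduce the input to rounding error.
    """
    x = np.asarray(x, dtype=np.float64)
    imfs: list[np.ndarray] = []
    sift_counts: list[int] = []
    warns: list[str] = []
    residue = x.copy()
    while len(imfs) < max_imfs:
        try:
            imf, residue_new, n_sifts, converged = extract_imf(
                residue, sd_threshold, max_sifts
            )
        except InsufficientExtremaError:
            break
        imfs.append(imf)
        sift_counts.append(n_sifts)
        if not converged:
            warns.append(f"IMF {len(imfs)}: sifting stopped at max_sifts={max_sifts}")
        residue = residue_new
    if len(imfs) < n_imfs_min:
        raise EmdError(
            f"only {len(imfs)} IMFs obtainable, {n_imfs_min} required"
        )
    return IMFDecomposition(imfs, residue, sift_counts, warns)


def combine_imf345(d: IMFDecomposition, indices: tuple[int, ...] = (3, 4, 5)) -> np.ndarray:
    """Pointwise sum of the IMFs at the given 1-based indices (default 3, 4, 5)."""
    if max(indices) > d.n_imfs:
        raise EmdError(
            f"decomposition has {d.n_imfs} IMFs, need index {max(indices)}"
        )
    return np.sum([d.imfs[i - 1] for i in indices], axis=0)
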