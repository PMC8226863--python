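"""R-peak detection, RR intervals, and half-RR beat segmentation.

The detector is a Pan-Tompkins-style chain: band-pass 5-15 Hz (where QRS
energy concentrates), differentiate, square, 150 ms moving-window integral,
adaptive threshold (mean + k*sd over a sliding 2 s window), 200 ms refractory
period, and a final snap to the local raw-signal maximum within +-50 ms.

Each interior beat is cut as the half-RR window before and after its R peak:
segment i spans [R_i - RR(i-1,i)/2, R_i + RR(i,i+1)/2), half-open, with the
half intervals floored to integer samples. The first and last peaks have no
half-RR neighbour on one side and produce no segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, filtfilt, find_peaks

from .exceptions import InsufficientDataError, InvalidArgumentError
from .signal import EcgSignal
from .synthetic import BeatClass

__all__ = ["RPeakList", "BeatSegment", "detect_r_peaks", "rr_intervals",
           "segment_beats", "match_peaks"]


@dataclass(frozen=True)
class RPeakList:
    """Ascending R-peak sample positions at a given sampling rate."""

    indices: np.ndarray
    fs: float
    refractory_s: float = 0.2

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.size > 1:
            gaps = np.diff(idx)
            if not np.all(gaps > 0):
                raise InvalidArgumentError("peak indices must be strictly increasing")
            if gaps.min() < self.refractory_s * self.fs:
                raise InvalidArgumentError(
                    f"peaks closer than the {self.refractory_s} s refractory period")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return self.indices.size


@dataclass(frozen=True)
class BeatSegment:
    """One cardiac cycle cut around an R peak."""

    samples: np.ndarray
    r_index_local: int
    r_index_global: int
    fs: float
    label: BeatClass | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.size < 2:
            raise InvalidArgumentError("a beat segment needs at least 2 samples")
        if not (0 <= self.r_index_local < arr.size):
            raise InvalidArgumentError("r_index_local must lie inside the segment")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size


def detect_r_peaks(signal: EcgSignal, k: float = 1.5,
                   refractory_s: float = 0.2) -> RPeakList:
    """Detect R peaks with the Pan-Tompkins-style chain described above.

    A flat (zero-variance) signal yields an empty peak list, not an error.

    Parameters
    ----------
    k : float
        Multiplier on the local standard deviation in the adaptive threshold.
    """
    fs = signal.fs
    if fs < 100:
        raise InvalidArgumentError("detector requires fs >= 100 Hz")
    if signal.duration < 2.0:
        raise InvalidArgumentError("detector requires at least 2 s of signal")
    x = signal.samples
    if np.ptp(x) == 0.0:
        return RPeakList(np.empty(0, dtype=np.int64), fs, refractory_s)

    # QRS energy emphasis
    b, a = butter(2, [5.0 / (fs / 2), 15.0 / (fs / 2)], btype="band")
    filtered = filtfilt(b, a, x)
    energy = np.gradient(filtered) ** 2
    mwi = uniform_filter1d(energy, max(1, int(round(0.150 * fs))))

    # adaptive threshold over a sliding 2 s window
    win = max(3, int(round(2.0 * fs)))
    local_mean = uniform_filter1d(mwi, win)
    local_sq = uniform_filter1d(mwi ** 2, win)
    local_sd = np.sqrt(np.maximum(local_sq - local_mean ** 2, 0.0))
    threshold = local_mean + k * local_sd

    candidates, _ = find_peaks(mwi, distance=max(1, int(round(refractory_s * fs))))
    candidates = candidates[mwi[candidates] >= threshold[candidates]]

    # snap to the raw-signal maximum within +-50 ms
    w = int(round(0.05 * fs))
    snapped = []
    for c in candidates:
        lo, hi = max(0, c - w), min(x.size, c + w + 1)
        snapped.append(lo + int(np.argmax(x[lo:hi])))
    # snapping can merge neighbours; enforce the refractory period keeping the
    # taller raw peak
    peaks: list[int] = []
    min_gap = refractory_s * fs
    for p in sorted(set(snapped)):
        if peaks and p - peaks[-1] < min_gap:
            if x[p] > x[peaks[-1]]:
                peaks[-1] = p
        else:
            peaks.append(p)
    return RPeakList(np.asarray(peaks, dtype=np.int64), fs, refractory_s)


def rr_intervals(peaks: RPeakList) -> np.ndarray:
    """Consecutive R-to-R intervals in seconds; length = n_peaks - 1."""
    if len(peaks) < 2:
        raise InsufficientDataError("need at least 2 peaks for an RR interval")
    return np.diff(peaks.indices) / peaks.fs


def segment_beats(signal: EcgSignal, peaks: RPeakList,
                  labels: list[BeatClass] | None = None) -> list[BeatSegment]:
    """Cut each interior beat as its half-RR window (see module docstring).

    ``labels``, if given, must carry one label per *peak*; interior segments
    inherit the label of their anchoring peak.
    """
    if len(peaks) < 3:
        raise InsufficientDataError("need >= 3 peaks (interior beats need both neighbours)")
    if labels is not None and len(labels) != len(peaks):
        raise InvalidArgumentError("one label per peak required")
    idx = peaks.indices
    segments = []
    for i in range(1, len(idx) - 1):
        start = int(idx[i] - (idx[i] - idx[i - 1]) // 2)
        stop = int(idx[i] + (idx[i + 1] - idx[i]) // 2)
        stop = min(stop, len(signal))
        segments.append(BeatSegment(
            samples=signal.samples[start:stop],
            r_index_local=int(idx[i] - start),
            r_index_global=int(idx[i]),
            fs=signal.fs,
            label=None if labels is None else labels[i],
        ))
    return segments


def match_peaks(detected: np.ndarray, truth: np.ndarray,
                tol_samples: int) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected vs ground-truth peaks.

    Returns (true positives, false positives, false negatives); a detection
    matches at most one truth peak within ``tol_samples``.
    """
    detected = np.asarray(detected, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    used = np.zeros(truth.size, dtype=bool)
    tp = 0
    for d in detected:
        dist = np.abs(truth - d)
        dist[used] = tol_samples + 1
        if dist.size and dist.min() <= tol_samples:
            used[int(np.argmin(dist))] = True
            tp += 1
    fp = detected.size - tp
    fn = truth.size - tp
    return tp, fp, fn
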