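"""Uniformly sampled single-lead ECG trace.

Conventions used everywhere in the package: voltages are millivolts, sample
indices are 0-based, and time ``t = index / fs`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidArgumentError


@dataclass(frozen=True)
class EcgSignal:
    """A uniformly sampled voltage trace from one ECG lead.

    Parameters
    ----------
    samples : array-like of float
        Voltages in millivolts. Must be finite and non-empty.
    fs : float
        Sampling rate in Hz, strictly positive.
    channel : str
        Lead/channel label (free text).
    source : str
        Provenance note (file path, generator call, ...).
    """

    samples: np.ndarray
    fs: float
    channel: str = "ECG"
    source: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1 or arr.size < 1:
            raise InvalidArgumentError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(arr)):
            raise InvalidArgumentError("samples must be finite")
        if not (self.fs > 0):
            raise InvalidArgumentError(f"fs must be > 0, got {self.fs}")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Recording length in seconds (n / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray, source: str | None = None) -> "EcgSignal":
        """Copy of this signal with new samples (same fs/channel)."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64),
                       source=self.source if source is None else source)
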