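"""Frequency-domain signal conditioning.

Two operations, both built on the real FFT of the full record:

* :func:`bandlimit` zeroes every spectral bin outside [low_hz, high_hz]
  (default 0.5-40 Hz, the band the front-end passes) and inverse-transforms;
* :func:`fft_threshold_denoise` additionally zeroes in-band bins whose
  magnitude falls below ``rel_threshold`` x the maximum in-band magnitude
  (default 0.2) — sub-threshold spectral content is treated as noise.

The DC bin is always removed (it lies below any positive low cut) and is
excluded from the maximum-magnitude search. Working on the half-spectrum via
rfft/irfft keeps the output exactly real without truncating an imaginary
residue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError
from .signal import EcgSignal

__all__ = ["FilterSpec", "bandlimit", "fft_threshold_denoise"]


@dataclass(frozen=True)
class FilterSpec:
    """Band limits (Hz) and the relative spectral-magnitude noise threshold."""

    low_hz: float = 0.5
    high_hz: float = 40.0
    rel_threshold: float = 0.2

    def validate(self, fs: float) -> None:
        if not (0 <= self.low_hz < self.high_hz):
            raise InvalidArgumentError("need 0 <= low_hz < high_hz")
        if self.high_hz >= fs / 2:
            raise InvalidArgumentError(f"high_hz must be below Nyquist ({fs / 2} Hz)")
        if not (0 <= self.rel_threshold < 1):
            raise InvalidArgumentError("rel_threshold must be in [0, 1)")


def _band_mask(n: int, fs: float, spec: FilterSpec) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= spec.low_hz) & (freqs <= spec.high_hz)
    mask[0] = False  # DC is always removed
    return mask


def bandlimit(signal: EcgSignal, spec: FilterSpec | None = None) -> EcgSignal:
    """Zero all spectral bins outside the pass band and inverse-transform."""
    spec = spec or FilterSpec()
    spec.validate(signal.fs)
    if len(signal) < 2:
        raise InvalidArgumentError("signal must have at least 2 samples")
    spectrum = np.fft.rfft(signal.samples)
    spectrum[~_band_mask(len(signal), signal.fs, spec)] = 0.0
    return signal.with_samples(np.fft.irfft(spectrum, n=len(signal)),
                               source=signal.source + "|bandlimit")


def fft_threshold_denoise(signal: EcgSignal, spec: FilterSpec | None = None) -> EcgSignal:
    """Band-limit, then zero in-band bins below the relative magnitude threshold.

    Bins are only ever zeroed, never amplified, so output energy cannot
    exceed input energy (Parseval). An all-zero signal is returned unchanged.
    """
    spec = spec or FilterSpec()
    spec.validate(signal.fs)
    if len(signal) < 2:
        raise InvalidArgumentError("signal must have at least 2 samples")
    spectrum = np.fft.rfft(signal.samples)
    mask = _band_mask(len(signal), signal.fs, spec)
    spectrum[~mask] = 0.0
    mags = np.abs(spectrum)
    peak = mags[mask].max() if mask.any() else 0.0
    if peak == 0.0:
        return signal.with_samples(np.fft.irfft(spectrum, n=len(signal)),
                                   source=signal.source + "|denoise")
    spectrum[mags < spec.rel_threshold * peak] = 0.0
    return signal.with_samples(np.fft.irfft(spectrum, n=len(signal)),
                               source=signal.source + "|denoise")
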