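"""Readers and writers for the signal formats the pipeline touches.

Three formats:

* a self-describing CSV stream (first line ``fs,<Hz>``, then one sample per
  line, millivolts);
* the WFDB dialect used by the MIT-BIH Arrhythmia Database (``.hea`` header,
  ``.dat`` signal in format 212, ``.atr`` beat annotations), written from the
  public format description;
* a plain-text serial stream emulating a 10-bit ADC front-end: one integer
  code per line, converted to millivolts by a fixed affine map.

Sample indices are 0-based; time t = index / fs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import FormatError, InvalidArgumentError
from .signal import EcgSignal

__all__ = [
    "AdcSpec",
    "read_csv", "write_csv",
    "read_serial_stream", "write_serial_stream",
    "read_wfdb", "write_wfdb",
    "read_wfdb_rpeaks", "write_wfdb_annotations",
    "BEAT_CODES",
]


# ---------------------------------------------------------------- CSV stream

def write_csv(path: str | Path, signal: EcgSignal) -> None:
    """Write ``fs,<Hz>`` then one millivolt sample per line."""
    lines = [f"fs,{signal.fs!r}"]
    lines += [repr(float(v)) for v in signal.samples]
    Path(path).write_text("\n".join(lines) + "\n")


def read_csv(path: str | Path) -> EcgSignal:
    """Read a CSV stream written by :func:`write_csv`.

    Raises :class:`FormatError` on a missing/malformed fs header or any
    non-numeric sample line (the message carries the 1-based line number).
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    head = lines[0].split(",")
    if len(head) != 2 or head[0].strip().lower() != "fs":
        raise FormatError(f"{path}: first line must be 'fs,<Hz>', got {lines[0]!r}")
    try:
        fs = float(head[1])
    except ValueError as exc:
        raise FormatError(f"{path}: unparseable fs {head[1]!r}") from exc
    samples = []
    for lineno, ln in enumerate(lines[1:], start=2):
        ln = ln.strip()
        if not ln:
            continue
        try:
            samples.append(float(ln))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric sample {ln!r}") from exc
    if not samples:
        raise FormatError(f"{path}: no samples")
    return EcgSignal(np.asarray(samples), fs=fs, source=str(path))


# ------------------------------------------------------------- serial stream

@dataclass(frozen=True)
class AdcSpec:
    """Affine code-to-millivolt map for the analog front-end.

    A ``bits``-wide converter over ``v_ref`` volts, with ``center_code``
    mapping to 0 mV: ``mV = (code - center_code) * 1000 * v_ref / 2**bits``.
    """

    bits: int = 10
    v_ref: float = 3.3
    center_code: int = 512

    def __post_init__(self) -> None:
        if not (0 <= self.center_code < 2 ** self.bits):
            raise InvalidArgumentError("center_code must satisfy 0 <= center < 2**bits")

    @property
    def mv_per_unit(self) -> float:
        return 1000.0 * self.v_ref / (2 ** self.bits)

    def to_mv(self, codes: np.ndarray) -> np.ndarray:
        return (codes.astype(np.float64) - self.center_code) * self.mv_per_unit

    def to_codes(self, mv: np.ndarray) -> np.ndarray:
        codes = np.round(mv / self.mv_per_unit + self.center_code).astype(np.int64)
        return np.clip(codes, 0, 2 ** self.bits - 1)


def read_serial_stream(path: str | Path, adc: AdcSpec | None = None,
                       fs: float = 360.0) -> EcgSignal:
    """Read one ADC code per line and convert to millivolts."""
    adc = adc or AdcSpec()
    path = Path(path)
    hi = 2 ** adc.bits
    codes = []
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        ln = ln.strip()
        if not ln:
            continue
        try:
            code = int(ln)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer code {ln!r}") from exc
        if not (0 <= code < hi):
            raise FormatError(f"{path}:{lineno}: code {code} outside [0, {hi})")
        codes.append(code)
    if not codes:
        raise FormatError(f"{path}: no samples")
    return EcgSignal(adc.to_mv(np.asarray(codes)), fs=fs, source=str(path))


def write_serial_stream(path: str | Path, signal: EcgSignal,
                        adc: AdcSpec | None = None) -> None:
    adc = adc or AdcSpec()
    codes = adc.to_codes(signal.samples)
    Path(path).write_text("\n".join(str(int(c)) for c in codes) + "\n")


# ----------------------------------------------------------- WFDB (.hea/.dat)

_FMT = 212          # 12-bit two's complement, two samples packed in 3 bytes
_GAIN = 200.0       # ADC units per mV (database convention)


def write_wfdb(record_path: str | Path, signals: list[EcgSignal],
               channel_names: list[str] | None = None) -> None:
    """Write a multi-channel record as ``<record>.hea`` + ``<record>.dat``.

    All signals must share fs and length. Values are quantised at the gain of
    200 ADC units/mV used by the database this dialect emulates.
    """
    record_path = Path(record_path)
    if not signals:
        raise InvalidArgumentError("at least one signal required")
    fs = signals[0].fs
    n = len(signals[0])
    if any(s.fs != fs or len(s) != n for s in signals):
        raise InvalidArgumentError("signals must share fs and length")
    names = channel_names or [s.channel for s in signals]
    if len(names) != len(signals):
        raise InvalidArgumentError("one channel name per signal required")

    adc = np.stack([np.round(s.samples * _GAIN).astype(np.int64) for s in signals])
    if adc.max() > 2047 or adc.min() < -2048:
        raise InvalidArgumentError("signal exceeds the 12-bit range at gain 200")

    dat_name = record_path.name + ".dat"
    lines = [f"{record_path.name} {len(signals)} {fs:g} {n}"]
    for ch, name in enumerate(names):
        first = int(adc[ch, 0])
        checksum = int(adc[ch].sum() & 0xFFFF)
        lines.append(f"{dat_name} {_FMT} {_GAIN:g} 12 0 {first} {checksum} 0 {name}")
    record_path.with_suffix(".hea").write_text("\n".join(lines) + "\n")

    # frame-interleave channels, then pack sample pairs into 3 bytes
    flat = adc.T.reshape(-1)
    if flat.size % 2:
        flat = np.concatenate([flat, [0]])
    u = (flat & 0xFFF).astype(np.uint16)  # two's complement in 12 bits
    s0, s1 = u[0::2], u[1::2]
    packed = np.empty(3 * s0.size, dtype=np.uint8)
    packed[0::3] = s0 & 0xFF
    packed[1::3] = ((s0 >> 8) & 0x0F) | (((s1 >> 8) & 0x0F) << 4)
    packed[2::3] = s1 & 0xFF
    record_path.with_suffix(".dat").write_bytes(packed.tobytes())


def _parse_header(record_path: Path) -> tuple[float, int, list[str], list[float], list[int]]:
    hea = record_path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"missing header {hea}")
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"{hea}: malformed record line {lines[0]!r}")
    try:
        n_sig, fs, n = int(head[1]), float(head[2]), int(head[3])
    except ValueError as exc:
        raise FormatError(f"{hea}: malformed record line {lines[0]!r}") from exc
    if len(lines) < 1 + n_sig:
        raise FormatError(f"{hea}: expected {n_sig} signal lines")
    names, gains, fmts = [], [], []
    for ln in lines[1:1 + n_sig]:
        parts = ln.split()
        if len(parts) < 2:
            raise FormatError(f"{hea}: malformed signal line {ln!r}")
        try:
            fmts.append(int(parts[1]))
        except ValueError as exc:
            raise FormatError(f"{hea}: malformed format in {ln!r}") from exc
        gain = _GAIN
        if len(parts) >= 3:
            # gain field may carry "(baseline)/units" decorations
            g = parts[2].split("(")[0].split("/")[0]
            gain = float(g) if g else _GAIN
        gains.append(gain or _GAIN)
        names.append(parts[-1])
    if any(f != _FMT for f in fmts):
        raise FormatError(f"{hea}: only format {_FMT} is supported")
    return fs, n, names, gains, [n_sig]


def read_wfdb(record_path: str | Path, channel: str | int = 0) -> EcgSignal:
    """Read one channel of a format-212 record, in millivolts.

    ``channel`` may be an index or a channel name from the header.
    Raises :class:`FormatError` for malformed files and ``KeyError`` for an
    unknown channel name.
    """
    record_path = Path(record_path)
    fs, n, names, gains, (n_sig,) = _parse_header(record_path)
    if isinstance(channel, str):
        if channel not in names:
            raise KeyError(f"channel {channel!r} not in {names}")
        ch = names.index(channel)
    else:
        ch = int(channel)
        if not (0 <= ch < n_sig):
            raise KeyError(f"channel index {ch} out of range (n_sig={n_sig})")

    raw = np.frombuffer(record_path.with_suffix(".dat").read_bytes(), dtype=np.uint8)
    if raw.size % 3:
        raise FormatError(f"{record_path}.dat: length not a multiple of 3")
    b0, b1, b2 = raw[0::3], raw[1::3], raw[2::3]
    s0 = b0.astype(np.int32) | ((b1 & 0x0F).astype(np.int32) << 8)
    s1 = b2.astype(np.int32) | ((b1 >> 4).astype(np.int32) << 8)
    flat = np.empty(2 * s0.size, dtype=np.int32)
    flat[0::2], flat[1::2] = s0, s1
    flat = np.where(flat > 2047, flat - 4096, flat)  # sign-extend 12 bits
    total = n * n_sig
    if flat.size < total:
        raise FormatError(f"{record_path}.dat: too short for {n} samples")
    frames = flat[:total].reshape(n, n_sig)
    return EcgSignal(frames[:, ch] / gains[ch], fs=fs,
                     channel=names[ch], source=str(record_path))


# -------------------------------------------------------- WFDB annotations

#: Annotation type codes counted as beats (normal + common ectopic/paced).
BEAT_CODES = frozenset(range(1, 14)) | {25, 34, 35, 38}

_SKIP, _EOF = 59, 0


def write_wfdb_annotations(record_path: str | Path, indices: np.ndarray,
                           code: int = 1) -> None:
    """Write beat annotations at the given sample indices to ``<record>.atr``."""
    indices = np.asarray(indices, dtype=np.int64)
    if indices.size > 1 and not np.all(np.diff(indices) > 0):
        raise InvalidArgumentError("annotation indices must be strictly ascending")
    if not (0 < code < 64):
        raise InvalidArgumentError("annotation code must be a 6-bit nonzero value")
    words = bytearray()

    def emit(c: int, data: int) -> None:
        w = ((c & 0x3F) << 10) | (data & 0x3FF)
        words.extend(w.to_bytes(2, "little"))

    prev = 0
    for idx in indices:
        dt = int(idx) - prev
        if dt >= 1024:
            emit(_SKIP, 0)
            words.extend(((dt >> 16) & 0xFFFF).to_bytes(2, "little"))
            words.extend((dt & 0xFFFF).to_bytes(2, "little"))
            dt = 0
            emit(code, 0)
        else:
            emit(code, dt)
        prev = int(idx)
    emit(_EOF, 0)
    Path(record_path).with_suffix(".atr").write_bytes(bytes(words))


def read_wfdb_rpeaks(record_path: str | Path,
                     beat_codes: frozenset[int] = BEAT_CODES) -> np.ndarray:
    """Read ``<record>.atr`` and return ascending beat-annotation sample indices."""
    atr = Path(record_path).with_suffix(".atr")
    if not atr.exists():
        raise FormatError(f"missing annotation file {atr}")
    raw = atr.read_bytes()
    if len(raw) % 2:
        raise FormatError(f"{atr}: odd byte count")
    out: list[int] = []
    t = 0
    pos = 0
    pending_skip = 0
    while pos + 1 < len(raw) or pos + 2 == len(raw):
        w = int.from_bytes(raw[pos:pos + 2], "little")
        pos += 2
        code, data = w >> 10, w & 0x3FF
        if code == _EOF and data == 0:
            break
        if code == _SKIP:
            if pos + 4 > len(raw):
                raise FormatError(f"{atr}: truncated skip interval")
            hi = int.from_bytes(raw[pos:pos + 2], "little")
            lo = int.from_bytes(raw[pos + 2:pos + 4], "little")
            pending_skip = (hi << 16) | lo
            pos += 4
            continue
        t += pending_skip + data
        pending_skip = 0
        if code in beat_codes:
            out.append(t)
    return np.asarray(out, dtype=np.int64)
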