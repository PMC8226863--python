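"""Deterministic beat-to-image rendering and labelled dataset building.

Each beat becomes a square grayscale raster (default 256 x 256): the time
axis is linearly resampled to the image width, and voltage is mapped through
a fixed global window (default [-1.5, +2.0] mV) to rows, clipping outside.
The trace is a 1-pixel connected polyline drawn black (0.0) on a white (1.0)
background. A fixed voltage window — rather than per-beat min-max scaling —
keeps ST-level shifts visible across images, which is exactly the feature
two of the four classes are defined by.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .exceptions import InvalidArgumentError
from .segmentation import BeatSegment
from .synthetic import BeatClass

__all__ = ["RenderSettings", "BeatImage", "voltage_to_row", "render_beat",
           "save_image", "load_image", "build_image_dataset",
           "load_manifest", "save_manifest"]


@dataclass(frozen=True)
class RenderSettings:
    """Raster size and the fixed millivolt window mapped onto image rows."""

    size: int = 256
    v_min: float = -1.5
    v_max: float = 2.0

    def __post_init__(self) -> None:
        if self.size < 32:
            raise InvalidArgumentError("image size must be >= 32")
        if not (self.v_min < self.v_max):
            raise InvalidArgumentError("need v_min < v_max")


@dataclass(frozen=True)
class BeatImage:
    """Square grayscale raster of one beat; intensities in [0, 1]."""

    pixels: np.ndarray
    source_beat: BeatSegment | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise InvalidArgumentError("pixels must be a square 2-D grid")
        if px.min() < 0 or px.max() > 1:
            raise InvalidArgumentError("intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def voltage_to_row(v: np.ndarray | float, settings: RenderSettings) -> np.ndarray:
    """Map voltage to image row (0 = top). Monotone: higher voltage, lower row."""
    v = np.clip(np.asarray(v, dtype=np.float64), settings.v_min, settings.v_max)
    frac = (settings.v_max - v) / (settings.v_max - settings.v_min)
    return np.round(frac * (settings.size - 1)).astype(np.int64)


def render_beat(beat: BeatSegment, size: int = 256,
                settings: RenderSettings | None = None) -> BeatImage:
    """Render one beat as a deterministic black-on-white polyline raster."""
    if settings is None:
        settings = RenderSettings(size=size)
    if len(beat) < 2:
        raise InvalidArgumentError("beat must have >= 2 samples")
    n = settings.size
    # resample the trace to one value per column
    x_src = np.linspace(0.0, 1.0, len(beat))
    x_dst = np.linspace(0.0, 1.0, n)
    values = np.interp(x_dst, x_src, beat.samples)
    rows = voltage_to_row(values, settings)

    pixels = np.ones((n, n), dtype=np.float32)
    pixels[rows, np.arange(n)] = 0.0
    # connect consecutive columns with vertical strokes so the polyline is
    # gapless regardless of slope
    for c in range(1, n):
        r0, r1 = rows[c - 1], rows[c]
        if abs(int(r1) - int(r0)) > 1:
            lo, hi = sorted((int(r0), int(r1)))
            pixels[lo + 1:hi, c] = 0.0
    return BeatImage(pixels=pixels, source_beat=beat)


def save_image(path: str | Path, image: BeatImage, fmt: str = "png") -> None:
    arr = np.round(image.pixels * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(str(path), format=fmt.upper())


def load_image(path: str | Path) -> np.ndarray:
    """Read an image back as a float32 grid in [0, 1]."""
    with Image.open(str(path)) as im:
        return np.asarray(im.convert("L"), dtype=np.float32) / 255.0


def build_image_dataset(beats: list[BeatSegment], out_dir: str | Path,
                        settings: RenderSettings | None = None,
                        fmt: str = "png",
                        source: str = "") -> dict:
    """Render labelled beats into per-class directories and write a manifest.

    Returns the manifest: ``{"entries": [{path, label, source}...],
    "counts": {label: n}, "size": int, "format": str}``. Paths in the
    manifest are relative to ``out_dir``.
    """
    settings = settings or RenderSettings()
    if fmt not in ("png", "jpg"):
        raise InvalidArgumentError("format must be png or jpg")
    out_dir = Path(out_dir)
    entries = []
    counts: dict[str, int] = {c.name: 0 for c in BeatClass}
    for i, beat in enumerate(beats):
        if beat.label is None:
            raise InvalidArgumentError(f"beat {i} is unlabeled")
        label = BeatClass(beat.label).name
        sub = out_dir / label.lower()
        sub.mkdir(parents=True, exist_ok=True)
        rel = f"{label.lower()}/beat_{i:06d}.{fmt}"
        save_image(out_dir / rel, render_beat(beat, settings=settings), fmt=fmt)
        entries.append({"path": rel, "label": label,
                        "source": source or f"beat@{beat.r_index_global}"})
        counts[label] += 1
    manifest = {"entries": entries, "counts": counts,
                "size": settings.size, "format": fmt}
    save_manifest(out_dir / "manifest.json", manifest)
    return manifest


def save_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1))


def load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def manifest_hash(manifest: dict) -> str:
    """Stable content hash of a manifest (paths + labels)."""
    key = json.dumps([(e["path"], e["label"]) for e in manifest["entries"]])
    return hashlib.sha256(key.encode()).hexdigest()[:16]
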