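"""Class balancing, 50/50 splitting, CNN training and evaluation.

The trainable architectures are conv-block stacks of the numpy network in
:mod:`.nn`; ``small_cnn`` is the lightweight default used for desk-scale
experiments, while ``resnet_tl`` / ``alexnet_tl`` / ``squeezenet_tl`` are
deeper presets standing in for the transfer-learned reference architectures
(their published total layer counts are carried as metadata for parity
reporting). Every preset runs from random initialisation; a locally stored
checkpoint can be loaded instead, so no weight download is ever required.

All dataset operations work on image manifests (see
:mod:`ecgpipe.imaging`): balancing downsamples each class without
replacement; the 50/50 split gives the *training* side the larger half of an
odd class (ceil(n/2) train, floor(n/2) test).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

from ..exceptions import InvalidArgumentError
from ..imaging import manifest_hash
from ..metrics import ConfusionTable
from ..synthetic import BeatClass
from . import nn

__all__ = ["TrainConfig", "TrainedModel", "ARCHITECTURES",
           "balance_classes", "split_half", "train", "evaluate",
           "load_images"]

_CLASS_ORDER = tuple(c.name for c in BeatClass)


@dataclass(frozen=True)
class ArchSpec:
    channels: tuple[int, ...]
    reference_layer_count: int | None  # published depth of the emulated net


ARCHITECTURES: dict[str, ArchSpec] = {
    "small_cnn": ArchSpec((8, 16, 32), None),
    "resnet_tl": ArchSpec((16, 32, 64, 64), 177),
    "alexnet_tl": ArchSpec((16, 32, 64), 25),
    "squeezenet_tl": ArchSpec((16, 16, 32, 32), 68),
}


@dataclass
class TrainConfig:
    """Training hyper-parameters; defaults suit the synthetic desk-scale runs."""

    architecture: str = "small_cnn"
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    split_fraction: float = 0.5
    balance_to: int | str = "min_class"
    input_size: int = 64          # images are resampled to this before the net
    init: str = "random"          # "random" | "checkpoint"
    checkpoint: str | None = None

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise InvalidArgumentError(
                f"unknown architecture {self.architecture!r}; "
                f"choose from {sorted(ARCHITECTURES)}")
        if not (0 < self.split_fraction < 1):
            raise InvalidArgumentError("split_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise InvalidArgumentError("epochs must be >= 1")
        if self.init not in ("random", "checkpoint"):
            raise InvalidArgumentError("init must be 'random' or 'checkpoint'")
        if self.init == "checkpoint" and not self.checkpoint:
            raise InvalidArgumentError("init='checkpoint' requires a checkpoint path")


# ------------------------------------------------------- manifest operations

def _entries_by_class(manifest: dict) -> dict[str, list[dict]]:
    by: dict[str, list[dict]] = {}
    for e in manifest["entries"]:
        by.setdefault(e["label"], []).append(e)
    return by


def _rebuild(manifest: dict, entries: list[dict]) -> dict:
    counts: dict[str, int] = {}
    for e in entries:
        counts[e["label"]] = counts.get(e["label"], 0) + 1
    out = dict(manifest)
    out["entries"] = entries
    out["counts"] = counts
    return out


def balance_classes(manifest: dict, n_per_class: int | str = "min_class",
                    seed: int = 0) -> dict:
    """Downsample every class to the same count, without replacement.

    ``n_per_class="min_class"`` uses the smallest class size. Deterministic
    for a fixed seed. A class smaller than an explicit request is an error.
    """
    by = _entries_by_class(manifest)
    if not by:
        raise InvalidArgumentError("empty manifest")
    if n_per_class == "min_class":
        n = min(len(v) for v in by.values())
    else:
        n = int(n_per_class)
        small = {lab: len(v) for lab, v in by.items() if len(v) < n}
        if small:
            raise InvalidArgumentError(f"classes smaller than {n}: {small}")
    rng = np.random.default_rng(seed)
    picked: list[dict] = []
    for lab in sorted(by):
        sel = rng.choice(len(by[lab]), size=n, replace=False)
        picked.extend(by[lab][i] for i in sorted(sel))
    return _rebuild(manifest, picked)


def split_half(manifest: dict, seed: int = 0,
               split_fraction: float = 0.5) -> tuple[dict, dict]:
    """Per-class random split; train receives ceil(n * fraction) of each class.

    At the default fraction the training half of an odd-sized class is the
    larger one (e.g. 5899 -> 2950 train / 2949 test). The halves are disjoint
    and their union is the input.
    """
    by = _entries_by_class(manifest)
    if any(len(v) < 2 for v in by.values()):
        bad = [lab for lab, v in by.items() if len(v) < 2]
        raise InvalidArgumentError(f"classes with < 2 items cannot be split: {bad}")
    rng = np.random.default_rng(seed)
    train_entries: list[dict] = []
    test_entries: list[dict] = []
    for lab in sorted(by):
        order = rng.permutation(len(by[lab]))
        n_train = int(np.ceil(len(order) * split_fraction))
        train_entries.extend(by[lab][i] for i in order[:n_train])
        test_entries.extend(by[lab][i] for i in order[n_train:])
    return _rebuild(manifest, train_entries), _rebuild(manifest, test_entries)


# ------------------------------------------------------------ image loading

def load_images(manifest: dict, root: str | Path,
                input_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Load manifest images as (N, 1, S, S) float32 in [0,1] plus label codes.

    Intensities are inverted at the loader (trace = foreground = 1, background
    = 0) so the sparse trace, not the white page, drives the features.
    """
    root = Path(root)
    xs, ys = [], []
    for e in manifest["entries"]:
        with Image.open(root / e["path"]) as im:
            im = im.convert("L").resize((input_size, input_size), Image.BILINEAR)
            xs.append(1.0 - np.asarray(im, dtype=np.float32) / 255.0)
        ys.append(BeatClass[e["label"]].value)
    x = np.stack(xs)[:, None, :, :]
    return x, np.asarray(ys, dtype=np.int64)


# ----------------------------------------------------------------- the model

def _build_net(arch: ArchSpec, input_size: int,
               rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    c_in = 1
    size = input_size
    for c_out in arch.channels:
        layers += [nn.Conv2d(c_in, c_out, rng), nn.ReLU(), nn.MaxPool2()]
        c_in = c_out
        size //= 2
        if size < 2:
            raise InvalidArgumentError("input_size too small for this architecture")
    # flatten (not global pooling): the classes differ by *where* the trace
    # lies in the frame (ST level, QRS width), so spatial position must
    # survive into the head
    layers += [nn.Flatten(), nn.Linear(c_in * size * size, len(_CLASS_ORDER), rng)]
    return nn.Sequential(layers)


@dataclass
class TrainedModel:
    """A trained four-class beat-image classifier.

    Serialisable to ``<path>.npz`` (parameters) + ``<path>.json`` (metadata);
    reloading reproduces predictions exactly.
    """

    architecture: str
    config: TrainConfig
    net: nn.Sequential
    class_order: tuple[str, ...]
    manifest_hash: str
    loss_history: list[float] = field(default_factory=list)

    @property
    def reference_layer_count(self) -> int | None:
        return ARCHITECTURES[self.architecture].reference_layer_count

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        probs = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.net.forward(x[i:i + batch_size])
            probs.append(nn.softmax(logits))
        return np.concatenate(probs)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 **{f"p{i}": p for i, p in enumerate(self.net.params)})
        meta = {
            "architecture": self.architecture,
            "config": asdict(self.config),
            "class_order": list(self.class_order),
            "manifest_hash": self.manifest_hash,
            "loss_history": self.loss_history,
            "format_version": 1,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        config = TrainConfig(**meta["config"])
        net = _build_net(ARCHITECTURES[config.architecture], config.input_size,
                         np.random.default_rng(config.seed))
        with np.load(path.with_suffix(".npz")) as data:
            for i, p in enumerate(net.params):
                p[...] = data[f"p{i}"]
        return cls(architecture=meta["architecture"], config=config, net=net,
                   class_order=tuple(meta["class_order"]),
                   manifest_hash=meta["manifest_hash"],
                   loss_history=list(meta["loss_history"]))


def train(train_manifest: dict, config: TrainConfig,
          root: str | Path) -> TrainedModel:
    """Train a four-class CNN on the manifest's images.

    All four classes must be present (the four-way head is fixed). Training
    is fully deterministic for a fixed config/seed.
    """
    present = {e["label"] for e in train_manifest["entries"]}
    missing = set(_CLASS_ORDER) - present
    if missing:
        raise InvalidArgumentError(f"training set is missing classes: {sorted(missing)}")

    x, y = load_images(train_manifest, root, config.input_size)
    rng = np.random.default_rng(config.seed)
    net = _build_net(ARCHITECTURES[config.architecture], config.input_size, rng)
    model = TrainedModel(architecture=config.architecture, config=config,
                         net=net, class_order=_CLASS_ORDER,
                         manifest_hash=manifest_hash(train_manifest))
    if config.init == "checkpoint":
        ref = TrainedModel.load(config.checkpoint)
        if ref.architecture != config.architecture:
            raise InvalidArgumentError("checkpoint architecture mismatch")
        for p, q in zip(net.params, ref.net.params):
            p[...] = q
    opt = nn.Adam(net.params, lr=config.learning_rate)
    n = x.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, config.batch_size):
            batch = order[i:i + config.batch_size]
            logits = net.forward(x[batch])
            loss, dlogits = nn.softmax_cross_entropy(logits, y[batch])
            net.backward(dlogits)
            opt.step(net.grads)
            epoch_loss += loss * batch.size
        model.loss_history.append(epoch_loss / n)
    return model


def evaluate(model: TrainedModel, test_manifest: dict,
             root: str | Path) -> ConfusionTable:
    """Predict the test manifest and aggregate a 4x4 confusion table."""
    for e in test_manifest["entries"]:
        if not e.get("label"):
            raise InvalidArgumentError(f"unlabeled test item: {e.get('path')}")
    x, y = load_images(test_manifest, root, model.config.input_size)
    pred = model.predict(x)
    counts = np.zeros((4, 4), dtype=np.int64)
    for t, p in zip(y, pred):
        counts[t, p] += 1
    return ConfusionTable(counts, model.class_order)
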