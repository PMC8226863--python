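"""Published benchmark numbers used as reference inputs.

Two small tables from a published four-class ECG beat-image classification
benchmark (transfer-learned ResNet, AlexNet and SqueezeNet evaluated on
MIT-BIH-derived beat images, 2949 test images per class):

* the per-architecture 4x4 confusion tables on the balanced test half, and
* the full per-class image counts before balancing.

They serve as fixed inputs for exercising and validating the metrics layer —
feeding the confusion tables through :mod:`ecgpipe.metrics` reproduces the
benchmark's reported accuracy, per-class recall/precision/F1, macro
aggregates and kappa.
"""

from __future__ import annotations

import numpy as np

from .metrics import ConfusionTable
from .synthetic import BeatClass

__all__ = ["BENCHMARK_CONFUSIONS", "CLASS_IMAGE_COUNTS", "benchmark_confusion"]

#: Full per-class beat-image counts of the benchmark's source data
#: (before balancing down to the smallest class).
CLASS_IMAGE_COUNTS: dict[BeatClass, int] = {
    BeatClass.QRS_WIDENING: 21377,
    BeatClass.SINUS_RHYTHM: 19751,
    BeatClass.ST_DEPRESSION: 7163,
    BeatClass.ST_ELEVATION: 5899,
}

# rows = true class, columns = predicted, in BeatClass order
_RESNET = [
    [2803, 30, 47, 69],
    [39, 2904, 3, 3],
    [54, 61, 2827, 7],
    [29, 6, 5, 2909],
]
_ALEXNET = [
    [2754, 56, 95, 44],
    [64, 2855, 26, 4],
    [43, 44, 2857, 5],
    [76, 6, 21, 2846],
]
_SQUEEZENET = [
    [2187, 128, 276, 358],
    [626, 2122, 86, 115],
    [311, 183, 2034, 421],
    [197, 75, 126, 2551],
]

BENCHMARK_CONFUSIONS: dict[str, ConfusionTable] = {
    "resnet": ConfusionTable(np.asarray(_RESNET)),
    "alexnet": ConfusionTable(np.asarray(_ALEXNET)),
    "squeezenet": ConfusionTable(np.asarray(_SQUEEZENET)),
}


def benchmark_confusion(architecture: str) -> ConfusionTable:
    """Confusion table of one benchmark architecture (resnet/alexnet/squeezenet)."""
    try:
        return BENCHMARK_CONFUSIONS[architecture.lower()]
    except KeyError as exc:
        raise KeyError(f"unknown architecture {architecture!r}; "
                       f"choose from {sorted(BENCHMARK_CONFUSIONS)}") from exc
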