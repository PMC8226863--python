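"""Multiclass confusion-table metrics: accuracy, recall/precision/F1, kappa.

Conventions
-----------
Rows of the confusion table are the true condition, columns the prediction,
in the fixed four-class order (QRS widening, sinus rhythm, ST depression,
ST elevation). Per class k:

    recall_k    = ct[k, k] / rowsum_k
    precision_k = ct[k, k] / colsum_k
    F1_k        = 2 * precision_k * recall_k / (precision_k + recall_k)

Macro recall/precision are unweighted class means. The *macro F1* reported
by default is the harmonic mean of macro precision and macro recall (the
convention the published benchmark tables in :mod:`ecgpipe.datasets` follow);
the mean of per-class F1 scores is available via ``f1_mode="mean_of_f1"`` —
the two differ in the third decimal on those tables. Cohen's kappa is the
chance-corrected agreement (p_o - p_e) / (1 - p_e) with p_e from the
row/column marginals.

A class with an empty row (no true items) has undefined recall; an empty
column gives undefined precision. These are reported as ``None`` and
flagged, never coerced to 0.
"""

from __future__ import annotations

import csv as _csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import InvalidArgumentError, UndefinedMetricError
from .synthetic import BeatClass

__all__ = ["ConfusionTable", "PerClassMetrics", "MetricsReport",
           "accuracy", "per_class_metrics", "macro_metrics", "cohens_kappa",
           "metrics_report"]

_DEFAULT_LABELS = tuple(c.name for c in BeatClass)


@dataclass(frozen=True)
class ConfusionTable:
    """K x K count table; rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple[str, ...] = _DEFAULT_LABELS

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise InvalidArgumentError("confusion table must be square")
        if arr.shape[0] != len(self.labels):
            raise InvalidArgumentError("one label per row required")
        if (arr < 0).any():
            raise InvalidArgumentError("counts must be non-negative")
        object.__setattr__(self, "counts", arr)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @classmethod
    def from_pairs(cls, true: list, predicted: list,
                   labels: tuple[str, ...] = _DEFAULT_LABELS) -> "ConfusionTable":
        """Aggregate (true, predicted) label pairs into a table."""
        if len(true) != len(predicted):
            raise InvalidArgumentError("true and predicted must align")
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(true, predicted):
            counts[index[str(t)], index[str(p)]] += 1
        return cls(counts, labels)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionTable":
        """Read a table written by :meth:`to_csv` (header row + label column)."""
        with open(path, newline="") as fh:
            rows = list(_csv.reader(fh))
        if len(rows) < 2:
            raise InvalidArgumentError(f"{path}: not a confusion table")
        labels = tuple(rows[0][1:])
        counts = [[int(v) for v in row[1:]] for row in rows[1:]]
        return cls(np.asarray(counts), labels)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = _csv.writer(fh)
            w.writerow(["true\\predicted", *self.labels])
            for lab, row in zip(self.labels, self.counts):
                w.writerow([lab, *[int(v) for v in row]])


@dataclass(frozen=True)
class PerClassMetrics:
    """Recall/precision/F1 for one class; ``None`` where undefined."""

    label: str
    recall: float | None
    precision: float | None
    f1: float | None

    @property
    def undefined(self) -> bool:
        return None in (self.recall, self.precision, self.f1)


def _check_nonempty(ct: ConfusionTable) -> None:
    if ct.total == 0:
        raise UndefinedMetricError("metrics are undefined for an all-zero table")


def accuracy(ct: ConfusionTable) -> float:
    """Overall correct rate: trace / total."""
    _check_nonempty(ct)
    return float(np.trace(ct.counts) / ct.total)


def per_class_metrics(ct: ConfusionTable) -> list[PerClassMetrics]:
    _check_nonempty(ct)
    rows = ct.counts.sum(axis=1)
    cols = ct.counts.sum(axis=0)
    out = []
    for k, lab in enumerate(ct.labels):
        tp = int(ct.counts[k, k])
        rec = tp / rows[k] if rows[k] > 0 else None
        prec = tp / cols[k] if cols[k] > 0 else None
        if rec is None or prec is None or (rec + prec) == 0:
            f1 = None
        else:
            f1 = 2 * prec * rec / (prec + rec)
        out.append(PerClassMetrics(lab, rec, prec, f1))
    return out


def macro_metrics(ct: ConfusionTable,
                  f1_mode: str = "harmonic_of_macros") -> tuple[float, float, float]:
    """Unweighted macro recall/precision, and macro F1 per ``f1_mode``.

    ``harmonic_of_macros`` (default): F1 of the macro precision/recall pair.
    ``mean_of_f1``: unweighted mean of the per-class F1 scores.
    """
    per = per_class_metrics(ct)
    if any(m.undefined for m in per):
        bad = [m.label for m in per if m.undefined]
        raise UndefinedMetricError(f"per-class metrics undefined for {bad}")
    macro_rec = float(np.mean([m.recall for m in per]))
    macro_prec = float(np.mean([m.precision for m in per]))
    if f1_mode == "harmonic_of_macros":
        macro_f1 = 2 * macro_prec * macro_rec / (macro_prec + macro_rec)
    elif f1_mode == "mean_of_f1":
        macro_f1 = float(np.mean([m.f1 for m in per]))
    else:
        raise InvalidArgumentError(f"unknown f1_mode {f1_mode!r}")
    return macro_rec, macro_prec, float(macro_f1)


def cohens_kappa(ct: ConfusionTable) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e)."""
    _check_nonempty(ct)
    total = ct.total
    p_o = np.trace(ct.counts) / total
    rows = ct.counts.sum(axis=1) / total
    cols = ct.counts.sum(axis=0) / total
    p_e = float(rows @ cols)
    if p_e >= 1.0:
        raise UndefinedMetricError("kappa undefined: chance agreement is 1")
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass(frozen=True)
class MetricsReport:
    """Full evaluation of one confusion table."""

    table: ConfusionTable
    accuracy: float
    per_class: tuple[PerClassMetrics, ...]
    macro_recall: float
    macro_precision: float
    macro_f1: float
    kappa: float
    f1_mode: str = "harmonic_of_macros"

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_recall": self.macro_recall,
            "macro_precision": self.macro_precision,
            "macro_f1": self.macro_f1,
            "kappa": self.kappa,
            "f1_mode": self.f1_mode,
            "per_class": {
                m.label: {"recall": m.recall, "precision": m.precision, "f1": m.f1}
                for m in self.per_class
            },
            "counts": self.table.counts.tolist(),
            "labels": list(self.table.labels),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def summary(self, per_class_digits: int = 3, overall_digits: int = 5) -> str:
        """Formatted text table (per-class at 3 d.p., aggregates at 5 d.p.)."""
        lines = [f"{'class':<14}{'recall':>9}{'precision':>11}{'F1':>9}"]
        for m in self.per_class:
            fmt = lambda v: "undef" if v is None else f"{v:.{per_class_digits}f}"
            lines.append(f"{m.label:<14}{fmt(m.recall):>9}{fmt(m.precision):>11}{fmt(m.f1):>9}")
        lines.append("-" * 43)
        for name, v in [("accuracy", self.accuracy),
                        ("macro recall", self.macro_recall),
                        ("macro precision", self.macro_precision),
                        ("macro F1", self.macro_f1),
                        ("kappa", self.kappa)]:
            lines.append(f"{name:<16}{v:.{overall_digits}f}")
        return "\n".join(lines)


def metrics_report(ct: ConfusionTable,
                   f1_mode: str = "harmonic_of_macros") -> MetricsReport:
    """Compute every metric for one table."""
    macro_rec, macro_prec, macro_f1 = macro_metrics(ct, f1_mode)
    return MetricsReport(
        table=ct,
        accuracy=accuracy(ct),
        per_class=tuple(per_class_metrics(ct)),
        macro_recall=macro_rec,
        macro_precision=macro_prec,
        macro_f1=macro_f1,
        kappa=cohens_kappa(ct),
        f1_mode=f1_mode,
    )
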