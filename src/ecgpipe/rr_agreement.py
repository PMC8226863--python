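"""Paired RR-interval agreement between two devices.

Given two aligned RR-interval series (e.g. a prototype single-lead monitor
against a reference patient monitor), this module provides

* a Wilcoxon signed-rank test (two-sided) with an exact null distribution
  for small samples and a tie/continuity-corrected normal approximation for
  larger ones,
* MA-plot coordinates (pairwise mean vs difference), and
* the fraction of pairs whose absolute difference lies within an agreement
  band (default +-0.1 s).

Zero differences are dropped before ranking (the classic Wilcoxon
convention); Pratt's method, which keeps them in the ranking, is available
via ``zero_method="pratt"``. Tied absolute differences receive midranks.

The exact path computes the full null distribution of W+ (sum of ranks of
positive differences under random signs) by a generating-polynomial
convolution over the observed ranks — identical to enumerating all 2^n sign
assignments, at polynomial cost — and is used for n <= 25.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import norm, rankdata

from .exceptions import InvalidArgumentError

__all__ = ["RRPairedSeries", "WilcoxonResult", "AgreementReport",
           "wilcoxon_signed_rank", "ma_points", "band_fraction",
           "agreement_report"]

EXACT_N_MAX = 25


@dataclass(frozen=True)
class RRPairedSeries:
    """Two aligned RR-interval series in seconds (pairwise comparison)."""

    rr_a: np.ndarray
    rr_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.rr_a, dtype=np.float64)
        b = np.asarray(self.rr_b, dtype=np.float64)
        if a.ndim != 1 or a.shape != b.shape:
            raise InvalidArgumentError("series must be 1-D and of equal length")
        if a.size < 1:
            raise InvalidArgumentError("need at least one pair")
        if (a <= 0).any() or (b <= 0).any():
            raise InvalidArgumentError("RR intervals must be positive")
        object.__setattr__(self, "rr_a", a)
        object.__setattr__(self, "rr_b", b)

    def __len__(self) -> int:
        return self.rr_a.size

    @classmethod
    def from_csv(cls, path_a: str | Path, path_b: str | Path | None = None) -> "RRPairedSeries":
        """Load from one two-column CSV, or two one-column files."""
        if path_b is None:
            data = np.loadtxt(path_a, delimiter=",", ndmin=2)
            if data.shape[1] != 2:
                raise InvalidArgumentError(f"{path_a}: expected two columns")
            return cls(data[:, 0], data[:, 1])
        return cls(np.loadtxt(path_a, ndmin=1), np.loadtxt(path_b, ndmin=1))


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float      # W+ (sum of ranks of positive differences)
    p_value: float        # two-sided
    n_used: int           # pairs after zero handling
    n_zero: int           # zero differences observed
    method: str           # "exact" or "approx"


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for W+ given the (mid)ranks of |differences|.

    The null distribution is symmetric around sum(ranks)/2; the two-sided p
    is the probability mass at least as far from the centre as the observed
    W+. Midranks are doubled so all sums are integers.
    """
    r2 = np.round(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    # distribution of 2*W+ over all sign assignments, by convolution
    dist = np.zeros(total + 1, dtype=np.float64)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= 2.0 ** len(r2)
    w2 = 2.0 * w_plus
    dev = abs(w2 - total / 2.0)
    support = np.arange(total + 1)
    # tolerance guards against float jitter in the deviation comparison
    p = dist[np.abs(support - total / 2.0) >= dev - 1e-9].sum()
    return float(min(1.0, p))


def _approx_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Normal approximation with continuity and tie corrections."""
    n = ranks.size
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: subtract sum(t^3 - t)/48 over groups of tied |d|
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts ** 3 - counts).sum() / 48.0
    if var <= 0:
        return 1.0
    dev = abs(w_plus - mean)
    z = (dev - 0.5) / np.sqrt(var)  # continuity correction
    return float(min(1.0, 2.0 * norm.sf(z)))


def wilcoxon_signed_rank(pairs: RRPairedSeries,
                         zero_method: str = "drop",
                         mode: str = "auto") -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired RR intervals.

    Parameters
    ----------
    zero_method : {"drop", "pratt"}
        "drop" removes zero differences before ranking; "pratt" ranks them
        but excludes their ranks from both sums.
    mode : {"auto", "exact", "approx"}
        "auto" uses the exact distribution for n <= 25 pairs after zero
        handling, the corrected normal approximation beyond.

    If every difference is zero the devices agree exactly and p = 1 by
    convention.
    """
    if zero_method not in ("drop", "pratt"):
        raise InvalidArgumentError(f"unknown zero_method {zero_method!r}")
    if mode not in ("auto", "exact", "approx"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    d = pairs.rr_a - pairs.rr_b
    n_zero = int((d == 0).sum())
    if zero_method == "drop":
        d = d[d != 0]
    if d.size == 0 or not np.any(d):
        return WilcoxonResult(0.0, 1.0, 0, n_zero, "degenerate")
    ranks = rankdata(np.abs(d))
    if zero_method == "pratt":
        keep = d != 0
        w_plus = float(ranks[keep & (d > 0)].sum())
        ranks_used = ranks[keep]
    else:
        w_plus = float(ranks[d > 0].sum())
        ranks_used = ranks
    n = ranks_used.size
    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_N_MAX)
    if use_exact:
        p = _exact_two_sided_p(ranks_used, w_plus)
        return WilcoxonResult(w_plus, p, n, n_zero, "exact")
    p = _approx_two_sided_p(ranks_used, w_plus)
    return WilcoxonResult(w_plus, p, n, n_zero, "approx")


def ma_points(pairs: RRPairedSeries) -> np.ndarray:
    """(mean, difference) = ((a+b)/2, a-b) per pair, order preserved."""
    mean = (pairs.rr_a + pairs.rr_b) / 2.0
    diff = pairs.rr_a - pairs.rr_b
    return np.column_stack([mean, diff])


def band_fraction(pairs: RRPairedSeries, band: float = 0.1) -> float:
    """Fraction of pairs with |a - b| <= band (seconds)."""
    if band <= 0:
        raise InvalidArgumentError("band must be > 0")
    return float(np.mean(np.abs(pairs.rr_a - pairs.rr_b) <= band))


@dataclass(frozen=True)
class AgreementReport:
    wilcoxon_statistic: float
    p_value: float
    n_pairs: int
    n_zero_diffs: int
    ma: np.ndarray
    band: float
    band_fraction: float

    def to_dict(self) -> dict:
        return {
            "wilcoxon_statistic": self.wilcoxon_statistic,
            "p_value": self.p_value,
            "n_pairs": self.n_pairs,
            "n_zero_diffs": self.n_zero_diffs,
            "band_s": self.band,
            "band_fraction": self.band_fraction,
            "ma_points": self.ma.tolist(),
        }


def agreement_report(pairs: RRPairedSeries, band: float = 0.1,
                     zero_method: str = "drop") -> AgreementReport:
    """Full device-agreement report: test, MA coordinates, band fraction."""
    res = wilcoxon_signed_rank(pairs, zero_method=zero_method)
    return AgreementReport(
        wilcoxon_statistic=res.statistic,
        p_value=res.p_value,
        n_pairs=len(pairs),
        n_zero_diffs=res.n_zero,
        ma=ma_points(pairs),
        band=band,
        band_fraction=band_fraction(pairs, band),
    )
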