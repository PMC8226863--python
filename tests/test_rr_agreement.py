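import itertools

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgpipe.exceptions import InvalidArgumentError
from ecgpipe.rr_agreement import (RRPairedSeries, agreement_report,
                                  band_fraction, ma_points,
                                  wilcoxon_signed_rank)


def pairs_from_diffs(diffs, base=1.0):
    b = np.full(len(diffs), base)
    return RRPairedSeries(b + np.asarray(diffs, float), b)


def brute_force_two_sided_p(diffs):
    """Enumerate all 2^n sign assignments of the signed-rank statistic."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    n = ranks.size
    w_obs = ranks[d > 0].sum()
    center = ranks.sum() / 2.0
    dev = abs(w_obs - center)
    hits = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - center) >= dev - 1e-9:
            hits += 1
    return hits / 2 ** n


class TestWilcoxon:
    def test_textbook_exact_case(self):
        """Five positive unit-spaced differences: W+ = 15, p = 2/32."""
        res = wilcoxon_signed_rank(pairs_from_diffs([1, 2, 3, 4, 5]))
        assert res.method == "exact"
        assert res.statistic == 15.0
        assert res.p_value == pytest.approx(0.0625)

    def test_identical_series_conventional_p_one(self):
        a = np.full(10, 0.8)
        res = wilcoxon_signed_rank(RRPairedSeries(a, a.copy()))
        assert res.p_value == 1.0
        assert res.n_zero == 10

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(4, 10))
    def test_exact_path_equals_brute_force_enumeration(self, seed, n):
        """The convolution-based exact null equals explicit enumeration over
        all 2^n sign vectors, including tied |differences|."""
        rng = np.random.default_rng(seed)
        diffs = np.round(rng.normal(0.01, 0.05, size=n), 2)
        diffs = diffs[diffs != 0]
        if diffs.size < 2:
            return
        pairs = pairs_from_diffs(diffs)
        res = wilcoxon_signed_rank(pairs, mode="exact")
        # enumerate on the realised float differences so ties match exactly
        realised = pairs.rr_a - pairs.rr_b
        assert res.p_value == pytest.approx(brute_force_two_sided_p(realised))

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_scipy_exact_and_approx(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.6, 1.2, size=20)
        b = a + rng.normal(0.01, 0.04, size=20)
        mine = wilcoxon_signed_rank(RRPairedSeries(a, b), mode="exact")
        ref = sps.wilcoxon(a, b, method="exact")
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)
        a = rng.uniform(0.6, 1.2, size=40)
        b = a + rng.normal(0.01, 0.04, size=40)
        mine = wilcoxon_signed_rank(RRPairedSeries(a, b))
        assert mine.method == "approx"
        ref = sps.wilcoxon(a, b, method="approx", correction=True)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_exact_and_approx_agree_near_boundary(self):
        """At n = 25 the two code paths give p within 0.01 of each other."""
        rng = np.random.default_rng(8)
        a = rng.uniform(0.6, 1.2, size=25)
        b = a + rng.normal(0.015, 0.05, size=25)
        pairs = RRPairedSeries(a, b)
        p_exact = wilcoxon_signed_rank(pairs, mode="exact").p_value
        p_approx = wilcoxon_signed_rank(pairs, mode="approx").p_value
        assert abs(p_exact - p_approx) < 0.01

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_reorder_invariance_and_swap_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.6, 1.2, size=12)
        b = a + rng.normal(0.02, 0.05, size=12)
        res = wilcoxon_signed_rank(RRPairedSeries(a, b))
        perm = rng.permutation(12)
        res_perm = wilcoxon_signed_rank(RRPairedSeries(a[perm], b[perm]))
        assert res.p_value == pytest.approx(res_perm.p_value)
        swapped = wilcoxon_signed_rank(RRPairedSeries(b, a))
        assert swapped.p_value == pytest.approx(res.p_value)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(InvalidArgumentError):
            RRPairedSeries(np.ones(3), np.ones(4))

    def test_pratt_zero_method_runs(self):
        res = wilcoxon_signed_rank(pairs_from_diffs([0, 0, 0.1, 0.2, -0.05]),
                                   zero_method="pratt")
        assert 0 <= res.p_value <= 1


class TestMaAndBand:
    def test_ma_definition(self):
        pts = ma_points(RRPairedSeries(np.array([1.0]), np.array([0.9])))
        assert pts[0, 0] == pytest.approx(0.95)
        assert pts[0, 1] == pytest.approx(0.1)

    def test_ma_antisymmetric_under_swap(self):
        a, b = np.array([1.0, 0.8, 0.9]), np.array([0.9, 0.85, 0.9])
        fwd = ma_points(RRPairedSeries(a, b))
        rev = ma_points(RRPairedSeries(b, a))
        assert np.allclose(fwd[:, 1], -rev[:, 1])
        assert np.allclose(fwd[:, 0], rev[:, 0])

    def test_band_fraction_counting(self):
        pairs = pairs_from_diffs([0.05, 0.15])
        assert band_fraction(pairs, 0.1) == 0.5
        assert band_fraction(pairs, 1e9) == 1.0
        assert band_fraction(RRPairedSeries(np.ones(4), np.ones(4))) == 1.0

    def test_band_must_be_positive(self):
        with pytest.raises(InvalidArgumentError):
            band_fraction(pairs_from_diffs([0.1]), 0.0)

    def test_agreement_report_fields(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.6, 1.0, 50)
        b = a + rng.normal(0, 0.03, 50)
        rep = agreement_report(RRPairedSeries(a, b))
        assert rep.n_pairs == 50
        assert 0 <= rep.p_value <= 1
        assert 0 <= rep.band_fraction <= 1
        assert rep.ma.shape == (50, 2)
        d = rep.to_dict()
        assert d["band_s"] == 0.1
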