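import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgpipe.datasets import BENCHMARK_CONFUSIONS, CLASS_IMAGE_COUNTS
from ecgpipe.exceptions import InvalidArgumentError, UndefinedMetricError
from ecgpipe.metrics import (ConfusionTable, accuracy, cohens_kappa,
                             macro_metrics, metrics_report, per_class_metrics)
from ecgpipe.synthetic import BeatClass

DIAG = ConfusionTable(np.diag([10, 10, 10, 10]))


def random_table(seed, total=200, k=4):
    rng = np.random.default_rng(seed)
    return ConfusionTable(rng.multinomial(total, np.full(k * k, 1 / (k * k))).reshape(k, k))


class TestBasics:
    def test_perfect_table(self):
        assert accuracy(DIAG) == 1.0
        assert cohens_kappa(DIAG) == 1.0
        assert all(m.recall == m.precision == m.f1 == 1.0
                   for m in per_class_metrics(DIAG))

    def test_uniform_table_has_zero_kappa(self):
        ct = ConfusionTable(np.full((4, 4), 5))
        assert cohens_kappa(ct) == pytest.approx(0.0)

    def test_all_zero_table_undefined(self):
        ct = ConfusionTable(np.zeros((4, 4), dtype=int))
        with pytest.raises(UndefinedMetricError):
            accuracy(ct)

    def test_empty_column_flags_precision_undefined(self):
        counts = np.diag([10, 10, 10, 0])
        counts[3, 0] = 10  # class 3 never predicted -> column 3 empty
        per = per_class_metrics(ConfusionTable(counts))
        assert per[3].precision is None and per[3].undefined
        with pytest.raises(UndefinedMetricError):
            macro_metrics(ConfusionTable(counts))

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ConfusionTable(np.array([[1, -1], [0, 1]]), ("a", "b"))


class TestBenchmarkReproduction:
    """The published benchmark's summary metrics recomputed from its
    confusion tables (accuracy/kappa/macro at 5 d.p., per-class at 3 d.p.)."""

    @pytest.mark.parametrize("arch,acc,kappa,prec,f1", [
        ("resnet", 0.97008, 0.96010, 0.97011, 0.97009),
        ("alexnet", 0.95897, 0.94529, 0.95907, 0.95902),
        ("squeezenet", 0.75398, 0.67198, 0.76291, 0.75842),
    ])
    def test_summary_metrics(self, arch, acc, kappa, prec, f1):
        r = metrics_report(BENCHMARK_CONFUSIONS[arch])
        assert r.accuracy == pytest.approx(acc, abs=1e-5)
        assert r.kappa == pytest.approx(kappa, abs=1e-5)
        assert r.macro_precision == pytest.approx(prec, abs=1e-5)
        assert r.macro_f1 == pytest.approx(f1, abs=1e-5)
        # balanced test halves: macro recall restates accuracy
        assert r.macro_recall == pytest.approx(r.accuracy, abs=1e-12)

    @pytest.mark.parametrize("cls,recall,precision,f1", [
        (BeatClass.QRS_WIDENING, 0.950, 0.958, 0.954),
        (BeatClass.SINUS_RHYTHM, 0.985, 0.968, 0.976),
        (BeatClass.ST_DEPRESSION, 0.959, 0.981, 0.970),
        (BeatClass.ST_ELEVATION, 0.986, 0.974, 0.980),
    ])
    def test_resnet_per_class(self, cls, recall, precision, f1):
        per = per_class_metrics(BENCHMARK_CONFUSIONS["resnet"])[cls.value]
        assert per.recall == pytest.approx(recall, abs=5e-4)
        assert per.precision == pytest.approx(precision, abs=5e-4)
        assert per.f1 == pytest.approx(f1, abs=5e-4)

    def test_macro_f1_convention_distinguishable(self):
        """Harmonic of macro P/R and mean of per-class F1 differ in the 5th
        decimal on the alexnet table; the default follows the former."""
        harm = metrics_report(BENCHMARK_CONFUSIONS["alexnet"]).macro_f1
        mean = metrics_report(BENCHMARK_CONFUSIONS["alexnet"],
                              f1_mode="mean_of_f1").macro_f1
        assert harm == pytest.approx(0.95902, abs=1e-5)
        assert mean < harm

    def test_row_sums_are_balanced_test_halves(self):
        for ct in BENCHMARK_CONFUSIONS.values():
            assert np.all(ct.counts.sum(axis=1) == 2949)

    def test_balanced_kappa_identity(self):
        """With equal row sums, p_e = 1/K exactly (rows are all 1/K and the
        column fractions sum to 1), so kappa = (acc - 1/K)/(1 - 1/K)."""
        for ct in BENCHMARK_CONFUSIONS.values():
            acc = accuracy(ct)
            k = ct.n_classes
            assert cohens_kappa(ct) == pytest.approx(
                (acc - 1 / k) / (1 - 1 / k), abs=1e-12)

    def test_class_counts_table(self):
        assert CLASS_IMAGE_COUNTS[BeatClass.ST_ELEVATION] == 5899
        assert min(CLASS_IMAGE_COUNTS.values()) == 5899


class TestProperties:
    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_oracle_equivalence_with_pair_recount(self, seed):
        """Metrics from aggregated counts equal metrics from the raw
        (true, predicted) pair list, cross-checked against scikit-learn."""
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(seed)
        labels = tuple(c.name for c in BeatClass)
        true = rng.integers(0, 4, size=300)
        pred = np.where(rng.random(300) < 0.7, true, rng.integers(0, 4, size=300))
        ct = ConfusionTable.from_pairs([labels[t] for t in true],
                                       [labels[p] for p in pred])
        assert np.array_equal(
            ct.counts, sklearn_metrics.confusion_matrix(true, pred, labels=range(4)))
        assert accuracy(ct) == pytest.approx(
            sklearn_metrics.accuracy_score(true, pred))
        assert cohens_kappa(ct) == pytest.approx(
            sklearn_metrics.cohen_kappa_score(true, pred))
        mine = [m.recall for m in per_class_metrics(ct)]
        theirs = sklearn_metrics.recall_score(true, pred, average=None,
                                              labels=range(4))
        assert np.allclose(mine, theirs)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_permutation_invariance(self, seed):
        """Permuting class order permutes per-class metrics and leaves
        accuracy and kappa unchanged."""
        ct = random_table(seed)
        rng = np.random.default_rng(seed + 1)
        perm = rng.permutation(4)
        permuted = ConfusionTable(ct.counts[np.ix_(perm, perm)],
                                  tuple(ct.labels[i] for i in perm))
        assert accuracy(permuted) == pytest.approx(accuracy(ct))
        assert cohens_kappa(permuted) == pytest.approx(cohens_kappa(ct))
        orig = {m.label: m.recall for m in per_class_metrics(ct) if m.recall is not None}
        perm_metrics = {m.label: m.recall for m in per_class_metrics(permuted)
                        if m.recall is not None}
        assert orig == perm_metrics

    def test_csv_round_trip(self, tmp_path):
        ct = BENCHMARK_CONFUSIONS["resnet"]
        ct.to_csv(tmp_path / "ct.csv")
        back = ConfusionTable.from_csv(tmp_path / "ct.csv")
        assert np.array_equal(back.counts, ct.counts)
        assert back.labels == ct.labels
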