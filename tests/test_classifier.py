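import numpy as np
import pytest

from ecgpipe.classifier import (ARCHITECTURES, TrainConfig, TrainedModel,
                                balance_classes, evaluate, load_images,
                                split_half, train)
from ecgpipe.classifier import nn
from ecgpipe.exceptions import InvalidArgumentError
from ecgpipe.metrics import accuracy
from ecgpipe.synthetic import BeatClass


def fake_manifest(counts: dict[str, int]) -> dict:
    entries = [{"path": f"{lab.lower()}/{i}.png", "label": lab, "source": "t"}
               for lab, n in counts.items() for i in range(n)]
    return {"entries": entries, "counts": dict(counts), "size": 64, "format": "png"}


FULL_COUNTS = {"QRS_WIDENING": 21377, "SINUS_RHYTHM": 19751,
               "ST_DEPRESSION": 7163, "ST_ELEVATION": 5899}


class TestBalance:
    def test_min_class_balancing_of_full_counts(self):
        """Unbalanced {21377, 19751, 7163, 5899} -> 4 x 5899."""
        out = balance_classes(fake_manifest(FULL_COUNTS), "min_class", seed=0)
        assert out["counts"] == {lab: 5899 for lab in FULL_COUNTS}

    def test_already_balanced_membership_unchanged(self):
        m = fake_manifest({lab: 12 for lab in FULL_COUNTS})
        out = balance_classes(m, "min_class", seed=1)
        assert sorted(e["path"] for e in out["entries"]) == \
            sorted(e["path"] for e in m["entries"])

    def test_request_exceeding_class_size_rejected(self):
        with pytest.raises(InvalidArgumentError):
            balance_classes(fake_manifest({"SINUS_RHYTHM": 5, "ST_ELEVATION": 20}), 10)

    def test_deterministic_under_seed(self):
        m = fake_manifest(FULL_COUNTS)
        a = balance_classes(m, 100, seed=5)
        b = balance_classes(m, 100, seed=5)
        assert a["entries"] == b["entries"]


class TestSplit:
    def test_odd_class_gives_larger_training_half(self):
        """5899 images split 50/50 -> 2950 train, 2949 test."""
        m = fake_manifest({"ST_ELEVATION": 5899})
        tr, te = split_half(m, seed=0)
        assert len(tr["entries"]) == 2950
        assert len(te["entries"]) == 2949

    def test_even_split(self):
        tr, te = split_half(fake_manifest({"SINUS_RHYTHM": 10}), seed=0)
        assert len(tr["entries"]) == len(te["entries"]) == 5

    def test_partition_property(self):
        m = fake_manifest({lab: n for lab, n in
                           zip(FULL_COUNTS, (31, 20, 17, 8))})
        tr, te = split_half(m, seed=3)
        tr_paths = {e["path"] for e in tr["entries"]}
        te_paths = {e["path"] for e in te["entries"]}
        assert tr_paths.isdisjoint(te_paths)
        assert tr_paths | te_paths == {e["path"] for e in m["entries"]}
        for lab, n in zip(FULL_COUNTS, (31, 20, 17, 8)):
            assert tr["counts"][lab] == int(np.ceil(n / 2))
            assert te["counts"][lab] == n // 2

    def test_singleton_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            split_half(fake_manifest({"SINUS_RHYTHM": 1}))


@pytest.fixture(scope="module")
def trained(small_image_dataset):
    root, manifest = small_image_dataset
    train_m, test_m = split_half(manifest, seed=0)
    cfg = TrainConfig(epochs=6, seed=0, input_size=48, batch_size=16)
    model = train(train_m, cfg, root)
    return root, model, train_m, test_m


class TestTraining:
    def test_loss_decreases_on_learnable_data(self, trained):
        _, model, _, _ = trained
        assert model.loss_history[-1] < model.loss_history[0]

    def test_probabilities_sum_to_one_untrained(self, small_image_dataset):
        """Softmax contract holds already at epoch 0 (random init)."""
        from ecgpipe.classifier.model import _build_net
        root, manifest = small_image_dataset
        x, _ = load_images(manifest, root, 48)
        net = _build_net(ARCHITECTURES["small_cnn"], 48, np.random.default_rng(0))
        probs = nn.softmax(net.forward(x[:8]))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.shape[1] == 4

    def test_confusion_row_sums_equal_test_counts(self, trained):
        root, model, _, test_m = trained
        ct = evaluate(model, test_m, root)
        expected = [test_m["counts"][lab] for lab in model.class_order]
        assert list(ct.counts.sum(axis=1)) == expected
        assert ct.total == len(test_m["entries"])

    def test_retrain_reproduces_identical_confusion(self, trained):
        root, model, train_m, test_m = trained
        model2 = train(train_m, model.config, root)
        ct1 = evaluate(model, test_m, root)
        ct2 = evaluate(model2, test_m, root)
        assert np.array_equal(ct1.counts, ct2.counts)

    def test_save_load_identical_predictions(self, trained, tmp_path):
        root, model, _, test_m = trained
        model.save(tmp_path / "m")
        back = TrainedModel.load(tmp_path / "m")
        x, _ = load_images(test_m, root, model.config.input_size)
        assert np.array_equal(model.predict(x), back.predict(x))

    def test_missing_class_rejected(self, small_image_dataset):
        root, manifest = small_image_dataset
        partial = {**manifest,
                   "entries": [e for e in manifest["entries"]
                               if e["label"] != "ST_ELEVATION"]}
        with pytest.raises(InvalidArgumentError):
            train(partial, TrainConfig(epochs=1, input_size=48), root)

    def test_preset_metadata(self):
        assert ARCHITECTURES["resnet_tl"].reference_layer_count == 177
        assert ARCHITECTURES["alexnet_tl"].reference_layer_count == 25
        assert ARCHITECTURES["squeezenet_tl"].reference_layer_count == 68

    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            TrainConfig(architecture="vgg")
        with pytest.raises(InvalidArgumentError):
            TrainConfig(split_fraction=1.5)
        with pytest.raises(InvalidArgumentError):
            TrainConfig(init="checkpoint")
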