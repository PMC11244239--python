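import numpy as np
import pytest

from strokeeg.errors import ParameterError
from strokeeg.evaluate import (
    TrainConfig,
    fold_result,
    make_folds,
    metrics,
    roc_auc,
    summarize,
    train,
)
from strokeeg.nn.layers import Network, Linear, ReLU, softmax_cross_entropy
from strokeeg.nn.vgg import ModelConfig, build_model

from .oracles import auc_concordance_oracle


class TestMakeFolds:
    IDS = [f"s{i}" for i in range(10)]
    LABELS = [0, 1] * 5

    def test_five_folds_of_two_subjects(self):
        folds = make_folds(self.IDS, self.LABELS, k=5, seed=0)
        assert len(folds) == 5
        assert all(len(test) == 2 for _, test in folds)

    def test_partition_property(self):
        folds = make_folds(self.IDS, self.LABELS, k=5, seed=0)
        tested = [s for _, test in folds for s in test]
        assert sorted(tested) == sorted(self.IDS)
        for train_ids, test_ids in folds:
            assert not set(train_ids) & set(test_ids)
            assert sorted(train_ids + test_ids) == sorted(self.IDS)

    def test_same_seed_same_folds(self):
        assert make_folds(self.IDS, self.LABELS, 5, 42) == \
            make_folds(self.IDS, self.LABELS, 5, 42)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            make_folds(self.IDS, [1] * 10, 5, 0)

    def test_epoch_level_mode_is_separate_and_partitions(self):
        from strokeeg.evaluate import make_epoch_folds_leakage_prone

        folds = make_epoch_folds_leakage_prone(20, [0, 1] * 10, k=5, seed=0)
        tested = np.sort(np.concatenate([te for _, te in folds]))
        assert np.array_equal(tested, np.arange(20))


class TestMetrics:
    def test_symmetric_example(self):
        acc, sen, spe = metrics(45, 5, 5, 45)
        assert (acc, sen, spe) == (90.0, 90.0, 90.0)

    def test_all_correct(self):
        acc, _, _ = metrics(10, 0, 0, 10)
        assert acc == 100.0

    def test_matches_formula_oracle_on_random_counts(self, rng):
        for _ in range(1000):
            tp, fn, fp, tn = rng.integers(0, 200, size=4)
            if tp + fn + fp + tn == 0:
                continue
            acc, sen, spe = metrics(tp, fn, fp, tn)
            assert acc == 100.0 * (tp + tn) / (tp + fn + fp + tn)
            if tp + fn:
                assert sen == 100.0 * tp / (tp + fn)
            else:
                assert np.isnan(sen)
            if tn + fp:
                assert spe == 100.0 * tn / (tn + fp)
            else:
                assert np.isnan(spe)

    def test_accuracy_identity_from_sen_spe(self, rng):
        for _ in range(100):
            tp, fn, fp, tn = rng.integers(1, 100, size=4)
            acc, sen, spe = metrics(tp, fn, fp, tn)
            total = tp + fn + fp + tn
            assert acc == pytest.approx((sen * (tp + fn) + spe * (tn + fp)) / total)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            metrics(0, 0, 0, 0)


class TestRocAuc:
    def test_perfect_ranking(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        assert roc_auc(scores, labels).auc == 1.0

    def test_random_scores_auc_near_half(self):
        aucs = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            scores = r.uniform(size=1000)
            labels = r.integers(0, 2, size=1000)
            if labels.min() == labels.max():
                continue
            aucs.append(roc_auc(scores, labels).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_matches_pairwise_concordance_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            scores = np.round(rng.uniform(size=n), 2)  # force some ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                auc_concordance_oracle(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=300)
        labels = rng.integers(0, 2, size=300)
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))


def _toy_data(rng, n=80):
    """Linearly separable toy images: class 1 is brighter."""
    y = rng.integers(0, 2, size=n)
    x = rng.normal(0, 0.3, size=(n, 3, 32, 32)).astype(np.float32)
    x += y[:, None, None, None].astype(np.float32) - 0.5
    return x, y.astype(np.int64)


class TestTrain:
    def test_zero_learning_rate_leaves_weights_unchanged(self, rng):
        net = build_model(ModelConfig(input_size=32, width_multiplier=1 / 16))
        before = net.state_dict()
        x, y = _toy_data(rng, 40)
        train(net, x, y, TrainConfig(batch_size=20, learning_rate=0.0,
                                     max_epochs=3, patience=2, seed=0))
        after = net.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_loss_decreases_on_separable_data(self, rng):
        net = build_model(ModelConfig(input_size=32, width_multiplier=1 / 16,
                                      init_seed=1))
        x, y = _toy_data(rng, 120)
        res = train(net, x, y, TrainConfig(batch_size=32, learning_rate=0.02,
                                           momentum=0.9, max_epochs=5,
                                           patience=5, seed=1))
        losses = res.train_losses[:5]
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_fits_separable_toy_set(self, rng):
        net = build_model(ModelConfig(input_size=32, width_multiplier=1 / 16,
                                      init_seed=2))
        x, y = _toy_data(rng, 120)
        train(net, x, y, TrainConfig(batch_size=32, learning_rate=0.02,
                                     momentum=0.9, max_epochs=10, patience=10,
                                     loss_floor=0.05, seed=2))
        acc = (net.predict(x) == y).mean()
        assert acc > 0.95

    def test_same_seed_reproducible(self, rng):
        x, y = _toy_data(rng, 60)
        finals = []
        for _ in range(2):
            net = build_model(ModelConfig(input_size=32, width_multiplier=1 / 16,
                                          init_seed=3))
            res = train(net, x, y, TrainConfig(batch_size=30, learning_rate=0.01,
                                               momentum=0.9, max_epochs=3,
                                               patience=3, seed=3))
            finals.append(res.train_losses[-1])
        assert finals[0] == finals[1]

    def test_empty_or_single_class_rejected(self, rng):
        net = build_model(ModelConfig(input_size=32, width_multiplier=1 / 16))
        x, _ = _toy_data(rng, 10)
        with pytest.raises(ParameterError):
            train(net, x, np.zeros(10, dtype=np.int64),
                  TrainConfig(max_epochs=1, batch_size=4, patience=1))


def test_fold_result_and_summary(rng):
    probs = np.array([0.9, 0.8, 0.2, 0.4, 0.7, 0.1])
    labels = np.array([1, 1, 0, 1, 0, 0])
    fr = fold_result(0, probs, labels)
    assert fr.tp + fr.fn + fr.fp + fr.tn == fr.n_eval == 6
    assert fr.tp == 2 and fr.fn == 1 and fr.fp == 1 and fr.tn == 2
    report = summarize([fr], seed=1)
    assert report.mean_acc == fr.acc
    payload = report.to_json()
    assert '"acc"' in payload
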