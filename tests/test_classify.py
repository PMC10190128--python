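"""Classification: splits, metrics, FFNN, LSTM, hyperparameter screen."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ladderflow import (FeatureTable, SequenceDataset, TrainConfig, evaluate,
                        hyperparameter_screen, split_dataset, train_ffnn,
                        train_lstm)
from ladderflow.classify import SplitError, resample_sequence
from ladderflow.nnet import LSTMClassifier


def make_sequences(n_per_class, length=32, rise0=0.1, rise1=0.3,
                   amp_mean=30.0, amp_sd=8.0, noise=1.0, seed=0):
    """Trapezoid pulse sequences whose classes differ only in rise-time
    fraction; the plateau amplitude distribution is identical."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    t = np.linspace(0, 1, length)
    for label, rise in ((0, rise0), (1, rise1)):
        for _ in range(n_per_class):
            amp = rng.lognormal(np.log(amp_mean), amp_sd / amp_mean)
            shape = np.interp(t, [0.05, 0.05 + rise, 0.95 - rise, 0.95],
                              [0, 1, 1, 0], left=0, right=0)
            seq = amp * shape[:, None] * np.ones((1, 3))
            seq = seq + rng.normal(0, noise, seq.shape)
            X.append(seq)
            y.append(label)
    return SequenceDataset(np.array(X), np.array(y))


class TestSplitDataset:
    def test_exact_fraction_sizes(self):
        y = np.repeat([0, 1], 100)
        tr, va, te = split_dataset(y, (0.70, 0.15, 0.15), seed=0)
        assert (len(tr), len(va), len(te)) == (140, 30, 30)
        for part in (tr, va, te):
            labels = y[part]
            assert (labels == 0).sum() == (labels == 1).sum()

    def test_same_seed_identical_partition(self):
        y = np.repeat([0, 1], 50)
        a = split_dataset(y, seed=7)
        b = split_dataset(y, seed=7)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa, pb)

    def test_large_uneven_class_counts_within_one_of_exact(self):
        y = np.concatenate([np.zeros(10_232, int), np.ones(16_376, int)])
        tr, va, te = split_dataset(y, (0.70, 0.15, 0.15), seed=1)
        for part, frac in zip((tr, va, te), (0.70, 0.15, 0.15)):
            for cls, n_cls in ((0, 10_232), (1, 16_376)):
                got = (y[part] == cls).sum()
                assert abs(got - frac * n_cls) <= 1

    def test_small_class_rejected(self):
        with pytest.raises(SplitError):
            split_dataset(np.array([0, 0, 0, 1, 1]), seed=0)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_disjoint_and_exhaustive_for_every_seed(self, seed):
        y = np.tile([0, 1], 40)
        tr, va, te = split_dataset(y, seed=seed)
        combined = np.concatenate([tr, va, te])
        assert len(np.unique(combined)) == len(combined) == len(y)


class TestEvaluate:
    def test_perfect_predictions(self):
        acc, cm = evaluate([0, 0, 1, 1], [0, 0, 1, 1])
        assert acc == 1.0
        assert np.array_equal(cm, [[2, 0], [0, 2]])

    def test_constant_predictions_on_balanced_set(self):
        acc, cm = evaluate([0] * 10, [0] * 5 + [1] * 5)
        assert acc == 0.5

    def test_matches_brute_force_tally(self):
        preds = [0, 1, 1, 0, 1, 0, 0, 1, 1, 1]
        labels = [0, 1, 0, 0, 1, 1, 0, 1, 0, 1]
        acc, cm = evaluate(preds, labels)
        counts = np.zeros((2, 2), int)
        for p, t in zip(preds, labels):
            counts[t, p] += 1
        assert np.array_equal(cm, counts)
        assert acc == pytest.approx(np.trace(counts) / 10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate([0, 1], [0])


class TestFFNN:
    def test_separable_classes_high_accuracy(self, rng):
        n = 400
        X = np.vstack([rng.normal(0, 1, (n, 3)), rng.normal(20, 1, (n, 3))])
        y = np.repeat([0, 1], n)
        cfg = TrainConfig(hidden_units_ffnn=10, max_epochs=40, seed=0)
        report = train_ffnn(FeatureTable(X, y), cfg)
        assert report.accuracy_test >= 0.99

    def test_identical_distributions_chance_level(self, rng):
        n = 1000
        X = rng.normal(0, 1, (2 * n, 3))
        y = np.repeat([0, 1], n)
        cfg = TrainConfig(hidden_units_ffnn=10, max_epochs=10, seed=0)
        report = train_ffnn(FeatureTable(X, y), cfg)
        assert 0.42 <= report.accuracy_test <= 0.58

    def test_report_confusion_consistent_with_accuracy(self, rng):
        n = 200
        X = np.vstack([rng.normal(0, 1, (n, 3)), rng.normal(3, 1, (n, 3))])
        y = np.repeat([0, 1], n)
        report = train_ffnn(FeatureTable(X, y),
                            TrainConfig(max_epochs=10, seed=3))
        cm = np.asarray(report.confusion_test)
        assert cm.sum() == 60  # 15% of 400
        assert report.accuracy_test == pytest.approx(np.trace(cm) / cm.sum())

    def test_adding_separating_feature_never_hurts(self, rng):
        n = 500
        X = rng.normal(0, 1, (2 * n, 2))
        y = np.repeat([0, 1], n)
        base = train_ffnn(FeatureTable(X, y),
                          TrainConfig(max_epochs=10, seed=5))
        X_plus = np.column_stack([X, y * 100.0 + rng.normal(0, 0.1, 2 * n)])
        plus = train_ffnn(FeatureTable(X_plus, y),
                          TrainConfig(max_epochs=10, seed=5))
        assert plus.accuracy_test >= base.accuracy_test


class TestLSTMCore:
    def test_gradients_match_numeric_differentiation(self):
        """Analytic BPTT gradients agree with central finite differences."""
        net = LSTMClassifier(input_dim=2, hidden_units=4, seed=0,
                             dropout=0.0)
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (3, 5, 2))
        y = np.array([0, 1, 0])
        cache = net._forward(X, train=False)
        grads = net._backward(cache, y)
        eps = 1e-6
        for key in ("Wx", "Wh", "b", "Wy", "by"):
            param = net.params[key]
            flat_idx = [0, param.size // 2, param.size - 1]
            for i in flat_idx:
                orig = param.flat[i]
                param.flat[i] = orig + eps
                up = net.loss(X, y)
                param.flat[i] = orig - eps
                down = net.loss(X, y)
                param.flat[i] = orig
                numeric = (up - down) / (2 * eps)
                assert grads[key].flat[i] == pytest.approx(numeric,
                                                           abs=1e-5)

    def test_divergence_raises(self):
        net = LSTMClassifier(input_dim=1, hidden_units=2, seed=0,
                             learning_rate=1e-3)
        X = np.full((4, 3, 1), np.nan)
        with pytest.raises(FloatingPointError):
            net.fit(X, np.array([0, 1, 0, 1]))


class TestTrainLSTM:
    def cfg(self, **kw):
        defaults = dict(lstm_hidden=16, batch_size=32, max_epochs=12,
                        patience=4, seed=0)
        defaults.update(kw)
        return TrainConfig(**defaults)

    def test_amplitude_separable_classes(self, rng):
        n, L = 150, 24
        X0 = rng.normal(0, 1, (n, L, 3))
        X1 = rng.normal(10, 1, (n, L, 3))
        data = SequenceDataset(np.vstack([X0, X1]), np.repeat([0, 1], n))
        report = train_lstm(data, self.cfg())
        assert report.accuracy_test >= 0.99

    def test_shuffled_labels_chance_level(self, rng):
        data = make_sequences(250, seed=3)
        y = rng.permutation(data.y)
        report = train_lstm(SequenceDataset(data.X, y),
                            self.cfg(max_epochs=6))
        assert 0.40 <= report.accuracy_test <= 0.60

    def test_seed_reproducibility(self):
        data = make_sequences(80, seed=5)
        r1 = train_lstm(data, self.cfg())
        r2 = train_lstm(data, self.cfg())
        assert r1.accuracy_test == r2.accuracy_test
        assert np.array_equal(r1.confusion_test, r2.confusion_test)

    def test_history_records_validation_trace(self):
        data = make_sequences(80, seed=6)
        report = train_lstm(data, self.cfg(max_epochs=5, patience=10))
        assert len(report.history) == 5
        assert all(0.0 <= h["val_accuracy"] <= 1.0 for h in report.history)


class TestHyperparameterScreen:
    def test_single_point_grid_matches_direct_training(self):
        data = make_sequences(80, seed=8)
        cfg = TrainConfig(lstm_hidden=8, batch_size=16, max_epochs=4,
                          patience=10, seed=2)
        table, traces = hyperparameter_screen(
            data, batch_sizes=(16,), learning_rates=(1e-3,),
            hidden_units=(8,), base_cfg=cfg)
        assert len(table) == 1
        direct = train_lstm(data, cfg)
        assert table.accuracy_test[0] == direct.accuracy_test
        assert (16, 1e-3, 8) in traces

    def test_full_grid_shape_and_ranges(self):
        data = make_sequences(30, length=12, seed=9)
        cfg = TrainConfig(max_epochs=2, patience=10, seed=0)
        table, _ = hyperparameter_screen(
            data, batch_sizes=(10, 100, 1000),
            learning_rates=(1e-2, 1e-3, 1e-4),
            hidden_units=(4, 8, 16), base_cfg=cfg)
        assert len(table) == 27
        assert table.accuracy_test.between(0, 1).all()

    def test_seed_stability_on_separable_problem(self, rng):
        n = 120
        X0 = rng.normal(0, 1, (n, 16, 3))
        X1 = rng.normal(8, 1, (n, 16, 3))
        data = SequenceDataset(np.vstack([X0, X1]), np.repeat([0, 1], n))
        accs = []
        for seed in (0, 1):
            cfg = TrainConfig(lstm_hidden=8, batch_size=32, max_epochs=8,
                              patience=4, seed=seed)
            accs.append(train_lstm(data, cfg).accuracy_test)
        assert abs(accs[0] - accs[1]) < 0.05


def test_resample_sequence_preserves_endpoints():
    seg = np.column_stack([np.linspace(0, 10, 50)] * 3)
    out = resample_sequence(seg, 16)
    assert out.shape == (16, 3)
    assert out[0, 0] == pytest.approx(0.0)
    assert out[-1, 0] == pytest.approx(10.0)
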