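"""Protocol contracts: splitting, window harvesting, optimization behaviour,
metrics against a counting oracle, paired t-tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ssvepnet as sv
from ssvepnet import nn, training


def counting_oracle(cm):
    """Per-class one-vs-rest rates recomputed by explicit enumeration of
    (true, predicted) pairs — independent of the vectorized implementation."""
    pairs = [(i, j) for i in range(4) for j in range(4)
             for _ in range(int(cm[i, j]))]
    out = {"sens": [], "spec": [], "prec": [], "f1": []}
    for k in range(4):
        tp = sum(1 for t, p in pairs if t == k and p == k)
        fn = sum(1 for t, p in pairs if t == k and p != k)
        fp = sum(1 for t, p in pairs if t != k and p == k)
        tn = sum(1 for t, p in pairs if t != k and p != k)
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
        for name, v in zip(("sens", "spec", "prec", "f1"), (sens, spec, prec, f1)):
            out[name].append(v * 100)
    acc = sum(1 for t, p in pairs if t == p) / len(pairs) * 100
    return acc, out


class TestSplitTrials:
    def test_100_trials_split_90_10(self):
        labels = np.repeat(np.arange(4), 25)
        tr, va = training.split_trials(labels, (9, 1), seed=0)
        assert len(tr) == 90 and len(va) == 10
        assert len(np.intersect1d(tr, va)) == 0
        assert len(np.union1d(tr, va)) == 100
        for k in range(4):
            assert np.sum(labels[va] == k) >= 2  # stratified

    def test_four_trials_even_split(self):
        labels = np.array([0, 1, 2, 3] * 2)
        tr, va = training.split_trials(labels, (1, 1), seed=0)
        assert sorted(np.bincount(labels[tr])) == [1, 1, 1, 1]
        assert sorted(np.bincount(labels[va])) == [1, 1, 1, 1]

    def test_same_seed_same_split(self):
        labels = np.repeat(np.arange(4), 25)
        a = training.split_trials(labels, (9, 1), seed=7)
        b = training.split_trials(labels, (9, 1), seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            training.split_trials(np.array([0, 1, 2, 3]), (9, 1), seed=0)


class TestHarvestWindows:
    @pytest.mark.parametrize("n_trials,per_trial,expected", [
        (90, 20, 1800), (100, 20, 2000), (10, 1, 10)])
    def test_window_counts(self, n_trials, per_trial, expected):
        trials = np.zeros((n_trials, 9, 1050))
        labels = np.arange(n_trials) % 4
        ws = sv.WindowSpec(d_samples=64)
        wnd, y = training.harvest_windows(trials, labels, ws, per_trial,
                                          np.random.default_rng(0))
        assert wnd.shape == (expected, 9, 64)
        assert len(y) == expected

    def test_labels_inherited_and_bank_applied(self, bank):
        rng = np.random.default_rng(1)
        trials = rng.normal(size=(4, 9, 1050))
        labels = np.array([3, 1, 0, 2])
        ws = sv.WindowSpec(d_samples=64)
        wnd, y = training.harvest_windows(trials, labels, ws, 2, rng, bank=bank)
        assert wnd.shape == (8, 4, 9, 64)
        assert np.array_equal(y, np.repeat(labels, 2))


@pytest.fixture(scope="module")
def tiny_sets(small_window_batch):
    windows, labels = small_window_batch
    return windows[:48], labels[:48], windows[48:64], labels[48:64]


class TestTrain:
    def test_zero_lr_leaves_parameters_unchanged(self, tiny_sets):
        Xtr, ytr, Xva, yva = tiny_sets
        m = sv.build_model(sv.ModelConfig(P=64), seed=0)
        before = [p.value.copy() for p in m.params()]
        cfg = training.TrainConfig(lr=0.0, batch_size=16, iterations=10,
                                   eval_every=5, seed=0)
        m, _ = training.train(m, Xtr, ytr, Xva, yva, cfg)
        for p, b in zip(m.params(), before):
            assert np.array_equal(p.value, b)

    def test_same_seed_identical_loss_curves(self, tiny_sets):
        Xtr, ytr, Xva, yva = tiny_sets
        curves = []
        for _ in range(2):
            m = sv.build_model(sv.ModelConfig(P=64), seed=1)
            cfg = training.TrainConfig(batch_size=16, iterations=15,
                                       eval_every=5, seed=1)
            _, hist = training.train(m, Xtr, ytr, Xva, yva, cfg)
            curves.append(hist["loss"])
        assert np.array_equal(curves[0], curves[1])

    def test_loss_decreases_over_short_run(self, tiny_sets):
        Xtr, ytr, Xva, yva = tiny_sets
        m = sv.build_model(sv.ModelConfig(P=64), seed=2)
        cfg = training.TrainConfig(batch_size=16, iterations=60,
                                   eval_every=20, seed=2)
        _, hist = training.train(m, Xtr, ytr, Xva, yva, cfg)
        assert np.mean(hist["loss"][-10:]) < np.mean(hist["loss"][:10])

    def test_best_validation_state_returned(self, tiny_sets):
        Xtr, ytr, Xva, yva = tiny_sets
        m = sv.build_model(sv.ModelConfig(P=64), seed=3)
        cfg = training.TrainConfig(batch_size=16, iterations=40,
                                   eval_every=10, seed=3)
        m, hist = training.train(m, Xtr, ytr, Xva, yva, cfg)
        final = np.mean(m.predict(Xva) == yva) * 100
        assert final == pytest.approx(max(hist["val_accuracy"]))


class TestMetrics:
    def test_worked_confusion_example(self):
        cm = np.array([[20, 5, 0, 0],
                       [0, 25, 0, 0],
                       [0, 0, 25, 0],
                       [0, 0, 0, 25]])
        rep = training.metrics_from_confusion(cm)
        assert rep.sensitivity[0] == pytest.approx(80.00, abs=0.005)
        assert rep.precision[1] == pytest.approx(83.33, abs=0.005)
        assert rep.f1[1] == pytest.approx(90.91, abs=0.005)
        assert rep.accuracy == pytest.approx(95.00, abs=1e-9)

    def test_perfect_predictions_all_100(self):
        y = np.repeat(np.arange(4), 10)
        rep = training.evaluate(y, y)
        assert rep.accuracy == 100.0
        assert np.all(rep.sensitivity == 100.0)
        assert np.all(rep.specificity == 100.0)
        assert np.all(rep.f1 == 100.0)

    def test_uniform_random_predictions_near_chance(self):
        rng = np.random.default_rng(0)
        y = np.repeat(np.arange(4), 500)
        pred = rng.integers(0, 4, size=2000)
        rep = training.evaluate(pred, y)
        assert rep.accuracy == pytest.approx(25.0, abs=3.0)

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            training.evaluate(np.array([]), np.array([]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 40), min_size=16, max_size=16))
    def test_metrics_match_counting_oracle(self, entries):
        cm = np.array(entries).reshape(4, 4)
        if cm.sum() == 0:
            cm[0, 0] = 1
        rep = training.metrics_from_confusion(cm)
        acc, oracle = counting_oracle(cm)
        assert rep.accuracy == pytest.approx(acc, abs=1e-9)
        for got, want in ((rep.sensitivity, oracle["sens"]),
                          (rep.specificity, oracle["spec"]),
                          (rep.precision, oracle["prec"]),
                          (rep.f1, oracle["f1"])):
            assert np.allclose(got, want, atol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_confusion_conserves_support(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 4, size=100)
        pred = rng.integers(0, 4, size=100)
        cm = training.confusion_matrix(y, pred)
        assert np.array_equal(cm.sum(axis=1), np.bincount(y, minlength=4))
        assert cm.sum() == 100


class TestPairedTTest:
    def test_symmetric_differences(self):
        res = training.paired_t_test([1.0, 3.0], [2.0, 2.0])  # diffs -1, +1
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_worked_example(self):
        # differences [1, 0, 2, 1]: t = 2.449, df = 3
        a = np.array([5.0, 4.0, 6.0, 5.0])
        b = a - np.array([1.0, 0.0, 2.0, 1.0])
        res = training.paired_t_test(a, b)
        assert res.t == pytest.approx(2.449, abs=0.001)
        assert res.df == 3
        assert 0 < res.p <= 1

    def test_zero_variance_rejected(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            training.paired_t_test(a, a)
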