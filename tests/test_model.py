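"""Network, training-loop, and baseline tests, including the
finite-difference gradient check for the hand-written BPTT."""

import numpy as np
import pytest

from icuward.cohort import ChannelStats
from icuward.channels import N_DYNAMIC
from icuward.model import (
    BaselineModel,
    ModelConfig,
    PreparedData,
    SequenceModel,
    make_balanced_batches,
    should_stop,
    summarize_for_baseline,
    train_baseline,
)
from icuward.nn import Adam, BiLSTMClassifier


def _toy_data(rng, n=60, t=8, separation=0.0, n_features=N_DYNAMIC):
    """Sequences whose mean level separates the classes by `separation`."""
    y = (np.arange(n) % 2).astype(float)
    X = rng.uniform(0.2, 0.8, size=(n, t, n_features))
    X += separation * y[:, None, None]
    X = np.clip(X, 0, 1)
    lengths = rng.integers(2, t + 1, size=n)
    for b in range(n):
        X[b, lengths[b]:] = 0.0
    static = rng.uniform(0, 1, size=(n, 1))
    return PreparedData(X, lengths, static, y, [f"P{i}" for i in range(n)])


class TestNetwork:
    def test_gradients_match_finite_differences(self, rng):
        net = BiLSTMClassifier(3, 1, hidden=4, static_width=3, head_width=5,
                               seed=2)
        B, T = 3, 6
        X = rng.random((B, T, 3))
        lengths = np.array([6, 4, 2])
        for b, ln in enumerate(lengths):
            X[b, ln:] = 0
        static = rng.random((B, 1))
        y = np.array([1.0, 0.0, 1.0])
        loss, grads = net.loss_and_grads(X, lengths, static, y, l2=0.01)
        eps = 1e-6
        for k, v in net.params.items():
            flat_indices = [0, v.size - 1, v.size // 2]
            for fi in flat_indices:
                idx = np.unravel_index(fi, v.shape)
                orig = v[idx]
                v[idx] = orig + eps
                lp, _ = net.loss_and_grads(X, lengths, static, y, l2=0.01)
                v[idx] = orig - eps
                lm, _ = net.loss_and_grads(X, lengths, static, y, l2=0.01)
                v[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert grads[k][idx] == pytest.approx(fd, rel=1e-4,
                                                      abs=1e-9), k

    def test_forward_probability_contract(self, rng):
        net = BiLSTMClassifier(N_DYNAMIC)
        X = rng.random((1, 1, N_DYNAMIC))
        p, _ = net.forward(X, np.array([1]), rng.random((1, 1)))
        assert 0.0 <= p[0] <= 1.0 and np.isfinite(p[0])

    def test_forward_deterministic(self, rng):
        net = BiLSTMClassifier(N_DYNAMIC)
        X = rng.random((4, 7, N_DYNAMIC))
        lengths = np.array([7, 5, 3, 1])
        static = rng.random((4, 1))
        p1, _ = net.forward(X, lengths, static)
        p2, _ = net.forward(X, lengths, static)
        assert np.array_equal(p1, p2)

    def test_padding_is_inert(self, rng):
        """Scores depend only on rows within each sequence's length."""
        net = BiLSTMClassifier(N_DYNAMIC)
        X = rng.random((2, 9, N_DYNAMIC))
        lengths = np.array([5, 9])
        static = rng.random((2, 1))
        p1, _ = net.forward(X, lengths, static)
        X2 = X.copy()
        X2[0, 5:] = 0.77  # garbage in the padded region
        p2, _ = net.forward(X2, lengths, static)
        assert p1[0] == pytest.approx(p2[0], abs=1e-12)
        assert p1[1] == p2[1]

    def test_parameter_count_closed_form(self):
        h, sw, hw, f = 20, 8, 16, N_DYNAMIC
        net = BiLSTMClassifier(f, 1, hidden=h, static_width=sw,
                               head_width=hw)
        lstm = 2 * (4 * (f * h + h * h + h))
        static = 1 * sw + sw
        head = (2 * h + sw) * hw + hw + hw * 1 + 1
        assert net.n_parameters() == lstm + static + head == 7057

    def test_batch_and_single_calls_agree(self, rng):
        net = BiLSTMClassifier(N_DYNAMIC)
        X = rng.random((3, 6, N_DYNAMIC))
        lengths = np.array([6, 6, 6])
        static = rng.random((3, 1))
        batch, _ = net.forward(X, lengths, static)
        singles = [net.forward(X[i:i + 1], lengths[i:i + 1],
                               static[i:i + 1])[0][0] for i in range(3)]
        assert np.allclose(batch, singles, atol=1e-12)


class TestBalancedBatches:
    def test_half_and_half_composition(self, rng):
        y = np.r_[np.ones(10), np.zeros(1000)]
        for batch in make_balanced_batches(y, 32, rng):
            assert len(batch) == 32
            assert y[batch].sum() == 16

    def test_each_negative_at_most_once_per_epoch(self, rng):
        y = np.r_[np.ones(10), np.zeros(1000)]
        seen = np.concatenate(make_balanced_batches(y, 32, rng))
        negs = seen[y[seen] == 0]
        assert len(negs) == len(set(negs.tolist()))

    def test_seed_determinism(self):
        y = np.r_[np.ones(5), np.zeros(100)]
        b1 = make_balanced_batches(y, 16, np.random.default_rng(3))
        b2 = make_balanced_batches(y, 16, np.random.default_rng(3))
        assert all(np.array_equal(a, b) for a, b in zip(b1, b2))

    def test_missing_class_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            make_balanced_batches(np.zeros(10), 4, rng)


class TestEarlyStopping:
    def test_flat_metric_halts_at_warmup_plus_patience(self):
        history = []
        for epoch in range(1, 300):
            history.append(0.7)
            if should_stop(history, warmup=100, patience=60):
                break
        assert epoch == 160

    def test_improvement_after_warmup_resets_the_clock(self):
        history = [0.5] * 120 + [0.9]  # best at epoch 121
        assert not should_stop(history, warmup=100, patience=60)
        history += [0.6] * 59
        assert not should_stop(history, 100, 60)
        history += [0.6]
        assert should_stop(history, 100, 60)

    def test_patience_must_be_below_max_epochs(self):
        with pytest.raises(ValueError, match="patience"):
            ModelConfig(max_epochs=10, patience=10)


def _stats():
    return ChannelStats(np.zeros(N_DYNAMIC), np.ones(N_DYNAMIC))


class TestSequenceTraining:
    def test_separable_task_learned_and_deterministic(self, rng):
        train = _toy_data(rng, n=120, separation=0.25)
        val = _toy_data(rng, n=40, separation=0.25)
        cfg = ModelConfig(max_epochs=12, warmup=3, patience=3, seed=5)
        m1 = SequenceModel(cfg, _stats()).fit(train, val)
        from icuward.evaluation import auroc
        assert auroc(val.y, m1.score(val)) > 0.95
        m2 = SequenceModel(cfg, _stats()).fit(train, val)
        assert np.array_equal(m1.score(val), m2.score(val))
        assert m1.history.val_auroc == m2.history.val_auroc

    def test_nonfinite_loss_aborts(self, rng):
        train = _toy_data(rng, n=40)
        val = _toy_data(rng, n=20)
        cfg = ModelConfig(max_epochs=2, warmup=1, patience=1, seed=5)
        model = SequenceModel(cfg, _stats())
        model.net.params["W2"][:] = np.inf
        with pytest.raises(FloatingPointError, match="non-finite"):
            model.fit(train, val)

    def test_l2_penalty_shrinks_weights(self, rng):
        train = _toy_data(rng, n=80, separation=0.2)
        val = _toy_data(rng, n=30, separation=0.2)
        norms = []
        for l2 in (0.0, 0.05):
            cfg = ModelConfig(max_epochs=10, warmup=9, patience=1, seed=7,
                              l2=l2)
            m = SequenceModel(cfg, _stats()).fit(train, val)
            norms.append(sum(float(np.sum(v ** 2))
                             for k, v in m.net.params.items()
                             if k.startswith("W")))
        assert norms[1] < norms[0]


class TestBaselines:
    def test_summary_is_last_row_plus_static(self, rng):
        data = _toy_data(rng, n=5)
        feats = summarize_for_baseline(data)
        assert feats.shape == (5, N_DYNAMIC + 1)
        for b in range(5):
            assert np.array_equal(feats[b, :N_DYNAMIC],
                                  data.X[b, data.lengths[b] - 1])

    def test_boosted_trees_fit_separable_toy(self, rng):
        train = _toy_data(rng, n=100, separation=0.3)
        model = train_baseline("boosted_trees", train, None, _stats(), seed=1)
        pred = model.score(train) > 0.5
        assert np.mean(pred == train.y) == 1.0

    def test_logistic_symmetric_data_near_zero_intercept(self, rng):
        n = 400
        X = np.zeros((n, 4, N_DYNAMIC))
        y = (np.arange(n) % 2).astype(float)
        offs = rng.normal(0, 0.1, size=(n // 2, 4, N_DYNAMIC))
        X[y == 1] = 0.5 + offs
        X[y == 0] = 0.5 - offs  # exactly mirrored classes
        data = PreparedData(X, np.full(n, 4), np.full((n, 1), 0.5), y,
                            [f"P{i}" for i in range(n)])
        model = train_baseline("logistic", data, None, _stats(), seed=1)
        assert abs(model.clf.intercept_[0]) < 0.3

    def test_same_seed_same_predictions(self, rng):
        train = _toy_data(rng, n=100, separation=0.2)
        m1 = train_baseline("boosted_trees", train, None, _stats(), seed=9)
        m2 = train_baseline("boosted_trees", train, None, _stats(), seed=9)
        assert np.array_equal(m1.score(train), m2.score(train))

    def test_single_class_rejected(self, rng):
        data = _toy_data(rng, n=10)
        data.y[:] = 0.0
        with pytest.raises(ValueError, match="single-class"):
            train_baseline("logistic", data, None, _stats())

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown baseline"):
            BaselineModel("svm", _stats())


class TestAdam:
    def test_quadratic_convergence(self):
        params = {"w": np.array([5.0, -3.0])}
        opt = Adam(params, lr=0.1)
        for _ in range(500):
            opt.step(params, {"w": 2 * params["w"]})
        assert np.allclose(params["w"], 0.0, atol=1e-3)
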