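"""Recurrence equations, the stacked-LSTM classifier, baselines, evaluation."""

import numpy as np
import pytest

from phenoseq.sequences import (
    RNNParams, LSTMParams, LSTMClassifierConfig, LSTMSequenceClassifier,
    rnn_step, lstm_step, train_lstm, classify_sequence,
    FrameVoteSVM, svm_baseline, SharedLabelCRF, crf_baseline,
    evaluate,
)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def brute_force_rnn(params, x, h_prev):
    """Element-by-element evaluation of the RNN update, no vectorisation."""
    H, D = params.W_xh.shape
    h = np.zeros(H)
    for i in range(H):
        s = params.b[i]
        for j in range(D):
            s += params.W_xh[i, j] * x[j]
        for j in range(H):
            s += params.W_hh[i, j] * h_prev[j]
        h[i] = np.tanh(s)
    O = params.W_hy.shape[0]
    y = np.zeros(O)
    for i in range(O):
        s = 0.0
        for j in range(H):
            s += params.W_hy[i, j] * h[j]
        y[i] = _sigmoid(s)
    return h, y


def brute_force_lstm(params, x, h_prev, c_prev):
    """Element-by-element evaluation of the LSTM gate equations."""
    H, D = params.W_xi.shape

    def gate(Wx, Wh, b, squash):
        out = np.zeros(H)
        for i in range(H):
            s = b[i]
            for j in range(D):
                s += Wx[i, j] * x[j]
            for j in range(H):
                s += Wh[i, j] * h_prev[j]
            out[i] = squash(s)
        return out

    i_t = gate(params.W_xi, params.W_hi, params.b_i, _sigmoid)
    f_t = gate(params.W_xf, params.W_hf, params.b_f, _sigmoid)
    o_t = gate(params.W_xo, params.W_ho, params.b_o, _sigmoid)
    g_t = gate(params.W_xc, params.W_hc, params.b_c, np.tanh)
    c_t = np.array([f_t[i] * c_prev[i] + i_t[i] * g_t[i] for i in range(H)])
    h_t = np.array([o_t[i] * np.tanh(c_t[i]) for i in range(H)])
    return h_t, c_t


def random_lstm_params(rng, H, D):
    m = lambda *s: rng.normal(0, 1, s)
    return LSTMParams(
        W_xi=m(H, D), W_hi=m(H, H), b_i=m(H),
        W_xf=m(H, D), W_hf=m(H, H), b_f=m(H),
        W_xo=m(H, D), W_ho=m(H, H), b_o=m(H),
        W_xc=m(H, D), W_hc=m(H, H), b_c=m(H))


class TestRNNStep:
    def test_zero_parameters_give_half_sigmoid_output(self):
        p = RNNParams(np.zeros((3, 2)), np.zeros((3, 3)), np.zeros((2, 3)), np.zeros(3))
        h, y = rnn_step(p, np.array([1.0, -2.0]), np.zeros(3))
        assert np.allclose(h, 0.0)
        assert np.allclose(y, 0.5)

    def test_scalar_hand_evaluation(self):
        p = RNNParams(np.array([[1.0]]), np.array([[0.5]]), np.array([[1.0]]),
                      np.array([0.0]))
        h, _ = rnn_step(p, np.array([1.0]), np.array([0.2]))
        assert h[0] == pytest.approx(np.tanh(1.1))

    def test_output_in_unit_interval(self):
        rng = np.random.default_rng(0)
        p = RNNParams(rng.normal(0, 2, (4, 3)), rng.normal(0, 2, (4, 4)),
                      rng.normal(0, 2, (2, 4)), rng.normal(0, 2, 4))
        _, y = rnn_step(p, rng.normal(0, 3, 3), rng.normal(0, 1, 4))
        assert ((y > 0) & (y < 1)).all()

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            H, D, O = rng.integers(1, 5, 3)
            p = RNNParams(rng.normal(0, 1, (H, D)), rng.normal(0, 1, (H, H)),
                          rng.normal(0, 1, (O, H)), rng.normal(0, 1, H))
            x, h0 = rng.normal(0, 1, D), rng.normal(0, 1, H)
            h, y = rnn_step(p, x, h0)
            hb, yb = brute_force_rnn(p, x, h0)
            assert np.abs(h - hb).max() <= 1e-10
            assert np.abs(y - yb).max() <= 1e-10


class TestLSTMStep:
    def test_zero_parameters_zero_memory(self):
        p = random_lstm_params(np.random.default_rng(0), 3, 2)
        zero = LSTMParams(**{k: np.zeros_like(v) for k, v in vars(p).items()})
        h, c = lstm_step(zero, np.ones(2), np.zeros(3), np.zeros(3))
        assert np.allclose(c, 0.0) and np.allclose(h, 0.0)

    def test_zero_parameters_halve_previous_memory(self):
        p = random_lstm_params(np.random.default_rng(0), 1, 1)
        zero = LSTMParams(**{k: np.zeros_like(v) for k, v in vars(p).items()})
        h, c = lstm_step(zero, np.zeros(1), np.zeros(1), np.array([2.0]))
        assert c[0] == pytest.approx(1.0)            # forget gate sigma(0)=0.5
        assert h[0] == pytest.approx(0.5 * np.tanh(1.0))

    def test_state_bounds(self):
        rng = np.random.default_rng(1)
        p = random_lstm_params(rng, 4, 3)
        h, c = lstm_step(p, rng.normal(0, 3, 3), rng.normal(0, 1, 4), rng.normal(0, 1, 4))
        assert (np.abs(h) < 1).all()

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            H, D = rng.integers(1, 5, 2)
            p = random_lstm_params(rng, H, D)
            x, h0, c0 = rng.normal(0, 1, D), rng.normal(0, 1, H), rng.normal(0, 1, H)
            h, c = lstm_step(p, x, h0, c0)
            hb, cb = brute_force_lstm(p, x, h0, c0)
            assert np.abs(h - hb).max() <= 1e-10
            assert np.abs(c - cb).max() <= 1e-10

    def test_saturated_forget_gate_erases_memory(self):
        rng = np.random.default_rng(3)
        p = random_lstm_params(rng, 3, 2)
        p.b_f[:] = -1e3
        p.W_xf[:] = 0.0
        p.W_hf[:] = 0.0
        x, h0 = rng.normal(0, 1, 2), rng.normal(0, 1, 3)
        _, c_a = lstm_step(p, x, h0, np.full(3, 5.0))
        _, c_b = lstm_step(p, x, h0, np.full(3, -5.0))
        assert np.abs(c_a - c_b).max() < 1e-12


class TestLSTMClassifier:
    @staticmethod
    def _slope_sequences(n, slope, rng, T=22, D=8):
        return [np.cumsum(np.full((T, D), slope) + rng.normal(0, 0.5, (T, D)), axis=0)
                for _ in range(n)]

    def test_learns_slope_separable_classes(self):
        rng = np.random.default_rng(0)
        train = self._slope_sequences(20, 0.5, rng) + self._slope_sequences(20, 1.0, rng)
        y = np.repeat([0, 1], 20)
        cfg = LSTMClassifierConfig(hidden=32, epochs=12, seed=5)
        clf = train_lstm(train, y, cfg)
        test = self._slope_sequences(10, 0.5, rng) + self._slope_sequences(10, 1.0, rng)
        acc = (clf.predict(test) == np.repeat([0, 1], 10)).mean()
        assert acc >= 0.9

    def test_same_seed_reproduces_loss_curve(self):
        rng = np.random.default_rng(1)
        train = self._slope_sequences(8, 0.5, rng) + self._slope_sequences(8, 1.0, rng)
        y = np.repeat([0, 1], 8)
        cfg = LSTMClassifierConfig(hidden=16, epochs=4, seed=9)
        h1 = train_lstm(train, y, cfg).history
        h2 = train_lstm(train, y, cfg).history
        assert h1 == h2

    def test_scores_normalised_and_truncation_tolerated(self):
        rng = np.random.default_rng(2)
        train = self._slope_sequences(8, 0.5, rng) + self._slope_sequences(8, 1.5, rng)
        clf = train_lstm(train, np.repeat([0, 1], 8),
                         LSTMClassifierConfig(hidden=16, epochs=2, seed=1))
        p_full = classify_sequence(clf, train[0])
        p_trunc = classify_sequence(clf, train[0][:3])
        for p in (p_full, p_trunc):
            assert p.sum() == pytest.approx(1.0, abs=1e-6)
            assert (p >= 0).all()

    def test_layer_forward_agrees_with_printed_recurrence(self):
        """The batched trainer layer must be the gate equations, exactly."""
        rng = np.random.default_rng(4)
        clf = LSTMSequenceClassifier(LSTMClassifierConfig(hidden=6, n_layers=1,
                                                          seed=3), 2, 5)
        layer = clf.layers[0]
        x = rng.normal(0, 1, (1, 7, 5)).astype(np.float32)
        outs, _ = layer.forward(x, np.ones((1, 7), dtype=bool))
        p = layer.to_params()
        h = np.zeros(6, dtype=np.float32)
        c = np.zeros(6, dtype=np.float32)
        for t in range(7):
            h, c = lstm_step(p, x[0, t].astype(np.float64), h, c)
            assert np.abs(outs[0, t] - h).max() < 1e-5

    def test_empty_sequence_rejected(self):
        clf = LSTMSequenceClassifier(LSTMClassifierConfig(hidden=8), 2, 3)
        with pytest.raises(ValueError):
            clf.predict_proba([np.zeros((0, 3))])


class TestSVMBaseline:
    @staticmethod
    def _clusters(rng, n, center):
        return [rng.normal(center, 0.3, (5, 4)) for _ in range(n)]

    def test_separable_classes_perfectly_classified(self):
        rng = np.random.default_rng(0)
        train = self._clusters(rng, 10, 0.0) + self._clusters(rng, 10, 4.0)
        model = svm_baseline(train, np.repeat([0, 1], 10))
        test = self._clusters(rng, 5, 0.0) + self._clusters(rng, 5, 4.0)
        assert (model.predict(test) == np.repeat([0, 1], 5)).all()

    def test_majority_vote_and_tie_break(self):
        rng = np.random.default_rng(1)
        train = self._clusters(rng, 10, 0.0) + self._clusters(rng, 10, 4.0)
        model = svm_baseline(train, np.repeat([0, 1], 10))
        a = rng.normal(0.0, 0.1, (1, 4))
        b = rng.normal(4.0, 0.1, (1, 4))
        seq_aab = np.vstack([a, a, b])
        assert model.predict([seq_aab])[0] == 0
        seq_ab = np.vstack([a, b])  # 1-1 tie -> lowest class index
        assert model.predict([seq_ab])[0] == 0

    def test_absent_class_raises(self):
        rng = np.random.default_rng(2)
        train = self._clusters(rng, 4, 0.0)
        with pytest.raises(ValueError):
            svm_baseline(train, np.array([0, 0, 2, 2]))


class TestSharedLabelCRF:
    def test_hand_constructed_parameters_reduce_to_frame_majority(self):
        # unaries are class indicators; strong uniform self-transitions
        crf = SharedLabelCRF(n_classes=3, d_in=3)
        crf.U = np.eye(3) * 5.0
        crf.A = np.eye(3) * 10.0
        seq = np.array([[1, 0, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        frame_major = np.bincount(seq.argmax(axis=1), minlength=3).argmax()
        assert crf.predict([seq])[0] == frame_major == 0

    def test_frame_duplication_preserves_prediction(self):
        rng = np.random.default_rng(0)
        crf = SharedLabelCRF(n_classes=4, d_in=6)
        crf.U = rng.normal(0, 1, (4, 6))
        crf.A = np.eye(4) * 2.0  # uniform self-reward: an additive constant per step
        seq = rng.normal(0, 1, (5, 6))
        doubled = np.vstack([seq, seq])
        assert np.isfinite(crf.sequence_scores(seq)).all()
        assert crf.predict([seq])[0] == crf.predict([doubled])[0]

    def test_learns_separable_sequences(self):
        rng = np.random.default_rng(3)
        mk = lambda c, n: [rng.normal(c, 0.5, (8, 5)) for _ in range(n)]
        train = mk(0.0, 12) + mk(2.0, 12)
        crf = crf_baseline(train, np.repeat([0, 1], 12))
        test = mk(0.0, 6) + mk(2.0, 6)
        assert (crf.predict(test) == np.repeat([0, 1], 6)).mean() >= 0.9


class TestEvaluate:
    def test_perfect_predictions_score_hundred(self):
        rep = evaluate(np.array([0, 1, 2, 0]), np.array([0, 1, 2, 0]),
                       ["a", "b", "c"])
        assert np.allclose(rep.per_class, 100.0)
        assert rep.average == pytest.approx(100.0)

    def test_confusion_rows_sum_to_class_support(self):
        truth = np.array([0, 0, 1, 1, 1, 2])
        pred = np.array([0, 1, 1, 1, 2, 2])
        rep = evaluate(pred, truth)
        assert (rep.confusion.sum(axis=1) == np.bincount(truth)).all()

    def test_macro_average_is_mean_of_per_class(self):
        truth = np.array([0, 0, 1, 1])
        pred = np.array([0, 1, 1, 1])
        rep = evaluate(pred, truth)
        assert rep.average == pytest.approx(np.mean([50.0, 100.0]))

    def test_unknown_class_in_predictions_raises(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0, 5]), np.array([0, 1]), ["a", "b"])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0]), np.array([0, 1]))
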