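"""Sequence classifiers over per-frame feature trajectories.

The core recurrences::

    RNN:   h(t) = phi( W_xh x(t) + W_hh h(t-1) + b )
           y(t) = sigma( W_hy h(t) )

    LSTM:  i_t  = sigma( W_xi x(t) + W_hi h(t-1) + b_i )
           f_t  = sigma( W_xf x(t) + W_hf h(t-1) + b_f )
           o_t  = sigma( W_xo x(t) + W_ho h(t-1) + b_o )
           c(t) = f_t . c(t-1) + i_t . phi( W_xc x(t) + W_hc h(t-1) + b_c )
           h(t) = o_t . phi( c(t) )

with phi = tanh, sigma the logistic sigmoid and ``.`` the element-wise
product.  ``rnn_step``/``lstm_step`` evaluate one time step exactly as
written; the trainable classifier stacks two LSTM layers (the second consumes
the first's hidden states), reads out class scores from the final step and is
optimised by SGD with momentum on softmax cross-entropy.

Baselines: a per-frame SVM with majority voting over the sequence, and a
shared-label linear-chain CRF over deep feature sequences (all frames of a
plant are constrained to one label, so a sequence's score for class k is the
sum of its per-frame unary scores plus (T-1) times the self-transition
reward).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.metrics import confusion_matrix

from . import _nnops as nn

__all__ = [
    "RNNParams", "LSTMParams", "LSTMClassifierConfig",
    "rnn_step", "lstm_step",
    "LSTMSequenceClassifier", "train_lstm", "classify_sequence",
    "FrameVoteSVM", "svm_baseline",
    "SharedLabelCRF", "crf_baseline",
    "EvaluationReport", "evaluate",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(z, dtype=np.result_type(z, np.float32))
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# printed recurrences

@dataclass
class RNNParams:
    """Plain-RNN parameters; hidden nonlinearity tanh, output sigmoid."""
    W_xh: np.ndarray  # (hidden, input)
    W_hh: np.ndarray  # (hidden, hidden)
    W_hy: np.ndarray  # (output, hidden)
    b: np.ndarray     # (hidden,)

    def __post_init__(self) -> None:
        h, d = self.W_xh.shape
        if self.W_hh.shape != (h, h) or self.W_hy.shape[1] != h or self.b.shape != (h,):
            raise ValueError("inconsistent RNN parameter shapes")


@dataclass
class LSTMParams:
    """LSTM gate parameters, one matrix/bias per symbol of the update rules."""
    W_xi: np.ndarray; W_hi: np.ndarray; b_i: np.ndarray
    W_xf: np.ndarray; W_hf: np.ndarray; b_f: np.ndarray
    W_xo: np.ndarray; W_ho: np.ndarray; b_o: np.ndarray
    W_xc: np.ndarray; W_hc: np.ndarray; b_c: np.ndarray

    def __post_init__(self) -> None:
        h, d = self.W_xi.shape
        for m in (self.W_xf, self.W_xo, self.W_xc):
            if m.shape != (h, d):
                raise ValueError("input-side matrices must share shape")
        for m in (self.W_hi, self.W_hf, self.W_ho, self.W_hc):
            if m.shape != (h, h):
                raise ValueError("hidden-side matrices must be square of hidden dim")
        for v in (self.b_i, self.b_f, self.b_o, self.b_c):
            if v.shape != (h,):
                raise ValueError("bias shape mismatch")


def rnn_step(params: RNNParams, x_t: np.ndarray, h_prev: np.ndarray):
    """One RNN update; returns (h_t, y_t) exactly per the recurrence."""
    h_t = np.tanh(params.W_xh @ x_t + params.W_hh @ h_prev + params.b)
    y_t = _sigmoid(params.W_hy @ h_t)
    return h_t, y_t


def lstm_step(params: LSTMParams, x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray):
    """One LSTM update; returns (h_t, c_t) exactly per the gate equations."""
    i_t = _sigmoid(params.W_xi @ x_t + params.W_hi @ h_prev + params.b_i)
    f_t = _sigmoid(params.W_xf @ x_t + params.W_hf @ h_prev + params.b_f)
    o_t = _sigmoid(params.W_xo @ x_t + params.W_ho @ h_prev + params.b_o)
    c_t = f_t * c_prev + i_t * np.tanh(params.W_xc @ x_t + params.W_hc @ h_prev + params.b_c)
    h_t = o_t * np.tanh(c_t)
    return h_t, c_t


# ---------------------------------------------------------------------------
# trainable stacked-LSTM classifier (batched, masked BPTT)

@dataclass
class LSTMClassifierConfig:
    n_layers: int = 2
    hidden: int = 256
    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.005
    batch_size: int = 32
    epochs: int = 30
    seed: int = 0
    readout: str = "final"   # or "mean" over valid steps
    grad_clip: float = 5.0

    def __post_init__(self) -> None:
        if min(self.n_layers, self.hidden, self.batch_size, self.epochs) <= 0 \
                or self.learning_rate <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.readout not in ("final", "mean"):
            raise ValueError("readout must be 'final' or 'mean'")


class _LSTMLayer:
    """Batched masked LSTM layer with packed [i|f|o|g] parameters."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator) -> None:
        self.hidden = hidden
        self.Wx = nn.glorot(rng, (4 * hidden, d_in), d_in, hidden)
        self.Wh = nn.glorot(rng, (4 * hidden, hidden), hidden, hidden)
        self.b = np.zeros(4 * hidden, dtype=np.float32)
        self.b[hidden:2 * hidden] = 1.0  # forget-gate bias init

    def forward(self, x: np.ndarray, mask: np.ndarray):
        """x (B,T,D), mask (B,T) -> H (B,T,hidden) of post-mask hidden states."""
        B, T, _ = x.shape
        H = self.hidden
        h = np.zeros((B, H), dtype=np.float32)
        c = np.zeros((B, H), dtype=np.float32)
        outs = np.empty((B, T, H), dtype=np.float32)
        cache = []
        for t in range(T):
            xt = x[:, t]
            z = xt @ self.Wx.T + h @ self.Wh.T + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            o = _sigmoid(z[:, 2 * H:3 * H])
            g = np.tanh(z[:, 3 * H:])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            m = mask[:, t:t + 1].astype(np.float32)
            cache.append((xt, h, c, i, f, o, g, c_new, m))
            h = m * h_new + (1 - m) * h
            c = m * c_new + (1 - m) * c
            outs[:, t] = h
        return outs, cache

    def backward(self, dH: np.ndarray, cache):
        """dH (B,T,hidden) grads on post-mask outputs -> (dx, grads dict)."""
        B, T, _ = dH.shape
        H = self.hidden
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.empty((B, T, self.Wx.shape[1]), dtype=np.float32)
        dh = np.zeros((B, H), dtype=np.float32)
        dc = np.zeros((B, H), dtype=np.float32)
        for t in range(T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, o, g, c_new, m = cache[t]
            dh = dh + dH[:, t]
            dh_new = dh * m
            dh_skip = dh * (1 - m)
            dc_new = dc * m
            dc_skip = dc * (1 - m)
            tc = np.tanh(c_new)
            do = dh_new * tc
            dc_new = dc_new + dh_new * o * (1 - tc ** 2)
            df = dc_new * c_prev
            di = dc_new * g
            dg = dc_new * i
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f), do * o * (1 - o),
                dg * (1 - g ** 2)], axis=1).astype(np.float32)
            dWx += dz.T @ xt
            dWh += dz.T @ h_prev
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx
            dh = dz @ self.Wh + dh_skip
            dc = dc_new * f + dc_skip
        return dx, {"Wx": dWx, "Wh": dWh, "b": db}

    def to_params(self) -> LSTMParams:
        """Expose the packed weights as the per-gate parameter collection."""
        H = self.hidden
        Wx, Wh, b = self.Wx, self.Wh, self.b
        sl = [slice(0, H), slice(H, 2 * H), slice(2 * H, 3 * H), slice(3 * H, 4 * H)]
        return LSTMParams(
            W_xi=Wx[sl[0]], W_hi=Wh[sl[0]], b_i=b[sl[0]],
            W_xf=Wx[sl[1]], W_hf=Wh[sl[1]], b_f=b[sl[1]],
            W_xo=Wx[sl[2]], W_ho=Wh[sl[2]], b_o=b[sl[2]],
            W_xc=Wx[sl[3]], W_hc=Wh[sl[3]], b_c=b[sl[3]])


class LSTMSequenceClassifier:
    """Two-layer LSTM sequence classifier with final-step softmax readout."""

    def __init__(self, config: LSTMClassifierConfig, n_classes: int, d_in: int) -> None:
        self.config = config
        self.n_classes = n_classes
        self.d_in = d_in
        rng = np.random.default_rng(config.seed)
        dims = [d_in] + [config.hidden] * config.n_layers
        self.layers = [_LSTMLayer(dims[i], config.hidden, rng)
                       for i in range(config.n_layers)]
        self.Wy = nn.glorot(rng, (config.hidden, n_classes), config.hidden, n_classes)
        self.by = np.zeros(n_classes, dtype=np.float32)
        self.scaler_mean = np.zeros(d_in, dtype=np.float32)
        self.scaler_std = np.ones(d_in, dtype=np.float32)
        self.history: list[float] = []
        self._rng = rng

    # -- helpers ----------------------------------------------------------
    def _pack(self, seqs: list[np.ndarray]):
        B = len(seqs)
        T = max(len(s) for s in seqs)
        x = np.zeros((B, T, self.d_in), dtype=np.float32)
        mask = np.zeros((B, T), dtype=bool)
        for i, s in enumerate(seqs):
            s = np.asarray(s, dtype=np.float32)
            if s.ndim != 2 or s.shape[1] != self.d_in:
                raise ValueError("sequence feature dimension mismatch")
            if len(s) == 0:
                raise ValueError("empty sequence")
            x[i, :len(s)] = (s - self.scaler_mean) / self.scaler_std
            mask[i, :len(s)] = True
        return x, mask

    def _forward(self, x: np.ndarray, mask: np.ndarray, want_cache: bool = False):
        caches = []
        h = x
        for layer in self.layers:
            h, c = layer.forward(h, mask)
            caches.append(c)
        lengths = mask.sum(axis=1)
        if self.config.readout == "final":
            pooled = h[np.arange(len(h)), lengths - 1]
        else:
            pooled = (h * mask[:, :, None]).sum(axis=1) / lengths[:, None]
        logits = pooled @ self.Wy + self.by
        if want_cache:
            return logits, (caches, h.shape, mask, lengths, pooled)
        return logits

    def _backward(self, dlogits: np.ndarray, cache):
        caches, hshape, mask, lengths, pooled = cache
        grads = {"Wy": pooled.T @ dlogits, "by": dlogits.sum(axis=0)}
        dpooled = dlogits @ self.Wy.T
        dH = np.zeros(hshape, dtype=np.float32)
        if self.config.readout == "final":
            dH[np.arange(len(dH)), lengths - 1] = dpooled
        else:
            dH += (dpooled[:, None, :] * mask[:, :, None]) / lengths[:, None, None]
        layer_grads = []
        for li in range(len(self.layers) - 1, -1, -1):
            dH, g = self.layers[li].backward(dH, caches[li])
            layer_grads.insert(0, g)
        return grads, layer_grads

    def _param_dict(self):
        params = {"Wy": self.Wy, "by": self.by}
        for i, layer in enumerate(self.layers):
            params[f"Wx{i}"] = layer.Wx
            params[f"Wh{i}"] = layer.Wh
            params[f"b{i}"] = layer.b
        return params

    # -- API --------------------------------------------------------------
    def fit(self, sequences: list[np.ndarray], labels: np.ndarray) -> "LSTMSequenceClassifier":
        labels = np.asarray(labels)
        allx = np.concatenate([np.asarray(s, dtype=np.float32) for s in sequences])
        self.scaler_mean = allx.mean(axis=0)
        self.scaler_std = np.maximum(allx.std(axis=0), 1e-6)
        cfg = self.config
        opt = nn.SGDMomentum(self._param_dict(), cfg.learning_rate, cfg.momentum,
                             cfg.weight_decay)
        n = len(sequences)
        for _ in range(cfg.epochs):
            order = self._rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                x, mask = self._pack([sequences[i] for i in idx])
                logits, cache = self._forward(x, mask, want_cache=True)
                loss, dlogits = nn.softmax_cross_entropy(logits, labels[idx])
                head_grads, layer_grads = self._backward(dlogits, cache)
                grads = dict(head_grads)
                for i, g in enumerate(layer_grads):
                    grads[f"Wx{i}"] = g["Wx"]
                    grads[f"Wh{i}"] = g["Wh"]
                    grads[f"b{i}"] = g["b"]
                nn.clip_grads(grads, cfg.grad_clip)
                opt.step(grads)
                losses.append(loss)
            self.history.append(float(np.mean(losses)))
        return self

    def predict_proba(self, sequences: list[np.ndarray]) -> np.ndarray:
        x, mask = self._pack(sequences)
        return nn.softmax(self._forward(x, mask))

    def predict(self, sequences: list[np.ndarray]) -> np.ndarray:
        return self.predict_proba(sequences).argmax(axis=1)  # ties -> lowest index


def train_lstm(sequences: list[np.ndarray], labels: np.ndarray,
               config: LSTMClassifierConfig | None = None,
               n_classes: int | None = None) -> LSTMSequenceClassifier:
    """Train the stacked-LSTM genotype classifier on feature sequences."""
    config = config or LSTMClassifierConfig()
    labels = np.asarray(labels)
    if len(sequences) == 0:
        raise ValueError("no training sequences")
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    d_in = int(np.asarray(sequences[0]).shape[1])
    clf = LSTMSequenceClassifier(config, n_classes, d_in)
    return clf.fit(sequences, labels)


def classify_sequence(classifier: LSTMSequenceClassifier, sequence: np.ndarray) -> np.ndarray:
    """Normalised class scores (sum 1) for one feature sequence."""
    return classifier.predict_proba([np.asarray(sequence)])[0]


# ---------------------------------------------------------------------------
# baselines

class FrameVoteSVM:
    """RBF-SVM on standardised per-frame features + majority vote per plant."""

    def __init__(self, C: float = 1.0, gamma: str | float = "scale") -> None:
        self.scaler = StandardScaler()
        self.svc = SVC(C=C, gamma=gamma, kernel="rbf")
        self.n_classes = 0

    def fit(self, sequences: list[np.ndarray], labels: np.ndarray) -> "FrameVoteSVM":
        labels = np.asarray(labels)
        self.n_classes = int(labels.max()) + 1
        present = np.unique(labels)
        if len(present) != self.n_classes:
            missing = sorted(set(range(self.n_classes)) - set(present.tolist()))
            raise ValueError(f"classes absent from training: {missing}")
        X = np.concatenate([np.asarray(s, dtype=float) for s in sequences])
        y = np.concatenate([np.full(len(s), lab) for s, lab in zip(sequences, labels)])
        self.svc.fit(self.scaler.fit_transform(X), y)
        return self

    def predict_frames(self, sequence: np.ndarray) -> np.ndarray:
        return self.svc.predict(self.scaler.transform(np.asarray(sequence, dtype=float)))

    def predict(self, sequences: list[np.ndarray]) -> np.ndarray:
        out = []
        for s in sequences:
            votes = np.bincount(self.predict_frames(s).astype(int),
                                minlength=self.n_classes)
            out.append(int(votes.argmax()))  # argmax tie-break: lowest index
        return np.array(out)


def svm_baseline(train_sequences: list[np.ndarray], labels: np.ndarray,
                 **svm_kwargs) -> FrameVoteSVM:
    """Fit the handcrafted-features SVM baseline (frame classifier + voter)."""
    return FrameVoteSVM(**svm_kwargs).fit(train_sequences, labels)


class SharedLabelCRF:
    """Linear-chain CRF under the one-label-per-plant constraint.

    With all frames of a sequence sharing one label, the joint score of class
    k reduces to ``sum_t (U x_t + u0)_k + (T - 1) * A[k, k]``; training
    maximises the conditional likelihood of the true shared label, and only
    the self-transition rewards receive gradient.  A full transition matrix
    can still be supplied for hand-constructed scoring.
    """

    def __init__(self, n_classes: int, d_in: int) -> None:
        self.U = np.zeros((n_classes, d_in))
        self.u0 = np.zeros(n_classes)
        self.A = np.zeros((n_classes, n_classes))
        self.scaler_mean = np.zeros(d_in)
        self.scaler_std = np.ones(d_in)

    def _standardise(self, seq: np.ndarray) -> np.ndarray:
        return (np.asarray(seq, dtype=float) - self.scaler_mean) / self.scaler_std

    def sequence_scores(self, sequence: np.ndarray) -> np.ndarray:
        seq = self._standardise(sequence)
        if len(seq) == 0:
            raise ValueError("empty sequence")
        unary = seq @ self.U.T + self.u0
        return unary.sum(axis=0) + (len(seq) - 1) * np.diag(self.A)

    def predict_proba(self, sequences: list[np.ndarray]) -> np.ndarray:
        return nn.softmax(np.stack([self.sequence_scores(s) for s in sequences]))

    def predict(self, sequences: list[np.ndarray]) -> np.ndarray:
        return np.stack([self.sequence_scores(s) for s in sequences]).argmax(axis=1)

    def fit(self, sequences: list[np.ndarray], labels: np.ndarray,
            lr: float = 0.05, momentum: float = 0.9, iterations: int = 400,
            l2: float = 1e-3) -> "SharedLabelCRF":
        labels = np.asarray(labels)
        allx = np.concatenate([np.asarray(s, dtype=float) for s in sequences])
        self.scaler_mean = allx.mean(axis=0)
        self.scaler_std = np.maximum(allx.std(axis=0), 1e-6)
        S = np.stack([self._standardise(s).sum(axis=0) for s in sequences])  # (N, D)
        T = np.array([len(s) for s in sequences], dtype=float)
        n, L = len(S), len(self.u0)
        onehot = np.eye(L)[labels]
        vU = np.zeros_like(self.U)
        vu0 = np.zeros_like(self.u0)
        vA = np.zeros(L)
        for _ in range(iterations):
            scores = S @ self.U.T + np.outer(T, self.u0) + np.outer(T - 1, np.diag(self.A))
            p = nn.softmax(scores)
            d = (p - onehot) / n  # gradient of mean negative log-likelihood
            gU = d.T @ S + l2 * self.U
            gu0 = (d * T[:, None]).sum(axis=0)
            gA = (d * (T - 1)[:, None]).sum(axis=0) + l2 * np.diag(self.A)
            vU = momentum * vU - lr * gU
            vu0 = momentum * vu0 - lr * gu0
            vA = momentum * vA - lr * gA
            self.U += vU
            self.u0 += vu0
            self.A[np.diag_indices(L)] += vA
        return self


def crf_baseline(train_sequences: list[np.ndarray], labels: np.ndarray,
                 n_classes: int | None = None, **fit_kwargs) -> SharedLabelCRF:
    """Fit the CNN+CRF baseline on deep feature sequences."""
    labels = np.asarray(labels)
    if len(train_sequences) == 0:
        raise ValueError("no training sequences")
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    d_in = int(np.asarray(train_sequences[0]).shape[1])
    return SharedLabelCRF(n_classes, d_in).fit(train_sequences, labels, **fit_kwargs)


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvaluationReport:
    """Per-class recall (%), macro average (%), and the confusion matrix."""
    class_names: list[str]
    per_class: np.ndarray
    average: float
    confusion: np.ndarray

    def to_dict(self) -> dict:
        d = {name: float(v) for name, v in zip(self.class_names, self.per_class)}
        d["Avg."] = float(self.average)
        return d

    def to_text(self) -> str:
        header = "".join(f"{n:>12}" for n in self.class_names) + f"{'Avg.':>12}"
        vals = "".join(f"{v:12.1f}" for v in self.per_class) + f"{self.average:12.1f}"
        return header + "\n" + vals


def evaluate(predictions: np.ndarray, truth: np.ndarray,
             class_names: list[str] | None = None) -> EvaluationReport:
    """Per-class accuracy (recall, %), macro average and confusion matrix."""
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError("predictions and truth must have equal length")
    L = int(true.max()) + 1
    if class_names is None:
        class_names = [f"class{i}" for i in range(L)]
    L = max(L, len(class_names))
    if pred.min() < 0 or pred.max() >= L:
        raise ValueError("prediction contains an unknown class index")
    conf = confusion_matrix(true, pred, labels=np.arange(L))
    support = conf.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(support > 0, np.diag(conf) / np.maximum(support, 1), np.nan) * 100.0
    avg = float(np.nanmean(per_class))
    return EvaluationReport(list(class_names), per_class, avg, conf)
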