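"""Minimal NumPy primitives for the compact CNN / LSTM used in this package.

Implements just what the models need — same-padded 3x3 convolution via
im2col, 2x2 max pooling, dense layers, softmax cross-entropy, and SGD with
momentum and L2 weight decay — with explicit backward passes.  Everything is
float32 and deterministic given the caller's RNG.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape).astype(F32)


class SGDMomentum:
    """v = mom*v - lr*(g + wd*w); w += v.  Weight decay skips 1-D params (biases)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, momentum: float,
                 weight_decay: float) -> None:
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.vel = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for k, w in self.params.items():
            g = grads[k]
            if self.weight_decay and w.ndim > 1:
                g = g + self.weight_decay * w
            self.vel[k] = self.momentum * self.vel[k] - self.lr * g
            w += self.vel[k]


# ---------------------------------------------------------------------------
# convolution (3x3, stride 1, same padding)

def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) with 1-pixel zero padding."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols, dtype=F32)


def conv3x3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """x (N,C,H,W), w (O,C,3,3), b (O,) -> y (N,O,H,W) and cache."""
    n, c, h, wd = x.shape
    o = w.shape[0]
    cols = _im2col(x)
    wf = w.reshape(o, -1).T  # (C*9, O)
    y = cols @ wf + b
    y = y.reshape(n, h, wd, o).transpose(0, 3, 1, 2)
    return y, (cols, w, x.shape)


def conv3x3_backward(dy: np.ndarray, cache):
    cols, w, xshape = cache
    n, c, h, wd = xshape
    o = w.shape[0]
    dyf = dy.transpose(0, 2, 3, 1).reshape(-1, o)  # (N*H*W, O)
    dwf = cols.T @ dyf  # (C*9, O)
    dw = dwf.T.reshape(w.shape)
    db = dyf.sum(axis=0)
    # dx = "full" correlation of dy with flipped kernels = same conv with W^T flipped
    wt = np.ascontiguousarray(w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
    dx, _ = conv3x3_forward(dy, wt, np.zeros(c, dtype=F32))
    return dx, dw, db


# ---------------------------------------------------------------------------
# pooling / activations / dense

def maxpool2_forward(x: np.ndarray):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(n, c, h // 2, w // 2, 4)
    arg = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    return y, (arg, x.shape)


def maxpool2_backward(dy: np.ndarray, cache):
    arg, xshape = cache
    n, c, h, w = xshape
    dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=F32)
    np.put_along_axis(dflat, arg[..., None], dy[..., None], axis=-1)
    dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dx.reshape(n, c, h, w)


def relu_forward(x: np.ndarray):
    y = np.maximum(x, 0)
    return y, x > 0


def relu_backward(dy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dy * mask


def dense_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    return x @ w + b, (x, w)


def dense_backward(dy: np.ndarray, cache):
    x, w = cache
    return dy @ w.T, x.T @ dy, dy.sum(axis=0)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(z - z.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean CE loss over the batch and gradient w.r.t. logits."""
    p = softmax(logits.astype(np.float64))
    n = len(labels)
    loss = -np.log(np.maximum(p[np.arange(n), labels], 1e-12)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(F32)


def clip_grads(grads: dict[str, np.ndarray], max_norm: float) -> None:
    """Global-norm gradient clipping, in place."""
    total = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads.values()))
    if total > max_norm:
        scale = F32(max_norm / (total + 1e-12))
        for g in grads.values():
            g *= scale
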