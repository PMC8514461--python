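"""Minimal neural-network primitives in numpy.

Dense, embedding, LSTM and bidirectional LSTM layers with hand-written
backward passes, inverted dropout, a fused softmax cross-entropy, and the
Adam optimizer.  Each layer caches its own forward activations; a forward
pass must be followed by at most one backward pass.  Everything is
deterministic given the ``numpy.random.Generator`` instances passed in.

Shapes: batch-first.  Sequence inputs are (N, T, D); per-step hidden states
are (N, H).
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)


def _glorot(rng: np.random.Generator, n_in: int, n_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=shape or (n_in, n_out))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        self.W = Param(_glorot(rng, n_in, n_out))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.data.T

    def params(self) -> list[Param]:
        return [self.W, self.b]


class TimeDense:
    """A Dense layer applied independently at every timestep of (N, T, D)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        self.inner = Dense(n_in, n_out, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, t, d = x.shape
        self._shape = (n, t)
        return self.inner.forward(x.reshape(n * t, d)).reshape(n, t, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, t = self._shape
        dx = self.inner.backward(dy.reshape(n * t, -1))
        return dx.reshape(n, t, -1)

    def params(self) -> list[Param]:
        return self.inner.params()


class Embedding:
    def __init__(self, vocab: int, dim: int, rng: np.random.Generator) -> None:
        self.table = Param(rng.normal(0.0, 0.1, size=(vocab, dim)))
        self._codes: np.ndarray | None = None

    def forward(self, codes: np.ndarray) -> np.ndarray:
        self._codes = codes
        return self.table.data[codes]

    def backward(self, dy: np.ndarray) -> None:
        np.add.at(self.table.grad, self._codes, dy)

    def params(self) -> list[Param]:
        return [self.table]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def params(self) -> list[Param]:
        return []


class Dropout:
    """Inverted dropout; identity when rate is 0 or at inference."""

    def __init__(self, rate: float) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = 1.0
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def params(self) -> list[Param]:
        return []


class LSTM:
    """Single-direction LSTM over (N, T, D) returning all hidden states.

    Gate layout in the fused weight matrices: input, forget, cell, output.
    The forget-gate bias is initialized to 1.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator) -> None:
        h = n_hidden
        self.n_hidden = h
        self.Wx = Param(_glorot(rng, n_in, h, shape=(n_in, 4 * h)))
        self.Wh = Param(_glorot(rng, h, h, shape=(h, 4 * h)))
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0
        self.b = Param(b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, t, _ = x.shape
        h = self.n_hidden
        self._x = x
        self._cache = []
        h_t = np.zeros((n, h))
        c_t = np.zeros((n, h))
        out = np.empty((n, t, h))
        for step in range(t):
            z = x[:, step] @ self.Wx.data + h_t @ self.Wh.data + self.b.data
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c_prev = c_t
            c_t = f * c_prev + i * g
            tc = np.tanh(c_t)
            h_prev = h_t
            h_t = o * tc
            out[:, step] = h_t
            self._cache.append((h_prev, c_prev, i, f, g, o, tc))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        n, t, _ = x.shape
        h = self.n_hidden
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, h))
        dc_next = np.zeros((n, h))
        for step in range(t - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[step]
            dh = dout[:, step] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.Wx.grad += x[:, step].T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, step] = dz @ self.Wx.data.T
            dh_next = dz @ self.Wh.data.T
            dc_next = dc * f
        return dx

    def params(self) -> list[Param]:
        return [self.Wx, self.Wh, self.b]


class BiLSTM:
    """Forward and backward LSTMs; outputs concatenated per timestep (N, T, 2H)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator) -> None:
        self.n_hidden = n_hidden
        self.fwd = LSTM(n_in, n_hidden, rng)
        self.bwd = LSTM(n_in, n_hidden, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(np.ascontiguousarray(x[:, ::-1]))[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h = self.n_hidden
        dxf = self.fwd.backward(np.ascontiguousarray(dout[:, :, :h]))
        dxb = self.bwd.backward(np.ascontiguousarray(dout[:, ::-1, h:]))
        return dxf + dxb[:, ::-1]

    def params(self) -> list[Param]:
        return self.fwd.params() + self.bwd.params()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    loss = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


class Adam:
    """Adaptive-moment gradient descent with bias correction."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
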