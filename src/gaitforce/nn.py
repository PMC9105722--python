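"""Minimal numpy neural-network core: BiLSTM, dense, dropout, Adam.

Implements exactly what the sequence regressor needs — bidirectional LSTM
layers, time-distributed fully connected layers with tanh activations,
inverted dropout, mean-squared-error loss and the Adam optimizer — with
explicit backpropagation through time.  Arrays are [T x B x F]
(time, batch, features) inside layers.

Everything is seeded and single-threaded numpy, so identical seeds give
identical weights, updates and predictions.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BiLSTMLayer", "DenseLayer", "DropoutLayer", "Network", "Adam", "mse_loss"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class _LSTMDirection:
    """One direction of an LSTM layer (gate order: input, forget, cell, output)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(in_dim)
        kh = 1.0 / np.sqrt(hidden)
        self.W = rng.uniform(-k, k, size=(in_dim, 4 * hidden))
        self.U = rng.uniform(-kh, kh, size=(hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.hidden = hidden
        self._cache: dict | None = None
        self.zero_grad()

    def params(self) -> list[np.ndarray]:
        return [self.W, self.U, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.dU, self.db]

    def zero_grad(self) -> None:
        self.dW = np.zeros_like(self.W)
        self.dU = np.zeros_like(self.U)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        T, B, _ = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((T, B, H))
        gates = np.empty((T, B, 4 * H))
        cs = np.empty((T, B, H))
        c_prevs = np.empty((T, B, H))
        h_prevs = np.empty((T, B, H))
        xw = x @ self.W + self.b  # [T,B,4H]
        for t in range(T):
            h_prevs[t] = h
            c_prevs[t] = c
            z = xw[t] + h @ self.U
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c = f * c_prevs[t] + i * g
            h = o * np.tanh(c)
            gates[t, :, :H] = i
            gates[t, :, H : 2 * H] = f
            gates[t, :, 2 * H : 3 * H] = g
            gates[t, :, 3 * H :] = o
            cs[t] = c
            hs[t] = h
        self._cache = {
            "x": x,
            "gates": gates,
            "cs": cs,
            "c_prevs": c_prevs,
            "h_prevs": h_prevs,
        }
        return hs

    def backward(self, dh_out: np.ndarray) -> np.ndarray:
        cache = self._cache
        x, gates, cs = cache["x"], cache["gates"], cache["cs"]
        c_prevs, h_prevs = cache["c_prevs"], cache["h_prevs"]
        T, B, _ = x.shape
        H = self.hidden
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        dz_all = np.empty((T, B, 4 * H))
        for t in range(T - 1, -1, -1):
            i = gates[t, :, :H]
            f = gates[t, :, H : 2 * H]
            g = gates[t, :, 2 * H : 3 * H]
            o = gates[t, :, 3 * H :]
            tc = np.tanh(cs[t])
            dh = dh_out[t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prevs[t]
            dg = dc * i
            dc_next = dc * f
            dz = dz_all[t]
            dz[:, :H] = di * i * (1.0 - i)
            dz[:, H : 2 * H] = df * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
            dz[:, 3 * H :] = do * o * (1.0 - o)
            dh_next = dz @ self.U.T
        # time-batched weight gradients (cheaper than per-step accumulation)
        self.dU += np.tensordot(h_prevs, dz_all, axes=([0, 1], [0, 1]))
        self.dW += np.tensordot(x, dz_all, axes=([0, 1], [0, 1]))
        self.db += dz_all.sum(axis=(0, 1))
        dx = dz_all @ self.W.T
        return dx


class BiLSTMLayer:
    """Bidirectional LSTM; output is the concatenation of both directions."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        if hidden < 1:
            raise ValueError("hidden size must be >= 1")
        self.fwd = _LSTMDirection(in_dim, hidden, rng)
        self.bwd = _LSTMDirection(in_dim, hidden, rng)
        self.out_dim = 2 * hidden

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[::-1])[::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        H = self.fwd.hidden
        dxf = self.fwd.backward(dy[:, :, :H])
        dxb = self.bwd.backward(dy[::-1, :, H:])[::-1]
        return dxf + dxb

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def grads(self):
        return self.fwd.grads() + self.bwd.grads()

    def zero_grad(self):
        self.fwd.zero_grad()
        self.bwd.zero_grad()


class DenseLayer:
    """Time-distributed fully connected layer, optional tanh activation."""

    def __init__(
        self, in_dim: int, out_dim: int, rng: np.random.Generator, tanh: bool = True
    ):
        if out_dim < 1:
            raise ValueError("out_dim must be >= 1")
        k = 1.0 / np.sqrt(in_dim)
        self.W = rng.uniform(-k, k, size=(in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.tanh = tanh
        self.out_dim = out_dim
        self._cache = None
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        y = x @ self.W + self.b
        if self.tanh:
            y = np.tanh(y)
        self._cache = (x, y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, y = self._cache
        if self.tanh:
            dy = dy * (1.0 - y * y)
        self.dW += np.tensordot(x, dy, axes=([0, 1], [0, 1]))
        self.db += dy.sum(axis=(0, 1))
        return dy @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def zero_grad(self):
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)


class DropoutLayer:
    """Inverted dropout; active only during training."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask

    def params(self):
        return []

    def grads(self):
        return []

    def zero_grad(self):
        pass


class Network:
    """A plain layer stack with [T x B x F] tensors."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch {p.shape} vs {w.shape}")
            p[...] = w


class Adam:
    """Adaptive moment estimation over a network's parameter list."""

    def __init__(
        self,
        net: Network,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in net.params()]
        self.v = [np.zeros_like(p) for p in net.params()]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.net.params(), self.net.grads(), self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over every element, and its gradient wrt pred."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    grad = 2.0 * diff / diff.size
    return loss, grad
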