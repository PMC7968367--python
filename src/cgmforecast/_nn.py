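"""Minimal NumPy neural-network kernels for the glucose forecaster.

Implements exactly what the forecaster needs — LSTM layers (full-sequence or
final-vector output), inverted dropout, dense layers and the Adam optimizer —
with hand-derived backward passes.  Everything is float32 and deterministic
given the caller's ``numpy.random.Generator``.

Gate layout inside the fused LSTM weight matrix is ``[i, f, g, o]`` acting on
the concatenation ``[h_prev, x]``; the forget-gate bias is initialized to 1.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    def params(self) -> list[tuple[str, np.ndarray]]:
        return []

    def grads(self) -> list[tuple[str, np.ndarray]]:
        return []


class LSTMLayer(Layer):
    """Single LSTM layer over (batch, time, features) input."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator, name: str):
        self.hidden = hidden
        self.name = name
        self.W = _glorot(rng, input_dim + hidden, 4 * hidden, (input_dim + hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden, dtype=DTYPE)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: dict | None = None

    def params(self):
        return [(f"{self.name}.W", self.W), (f"{self.name}.b", self.b)]

    def grads(self):
        return [(f"{self.name}.W", self.dW), (f"{self.name}.b", self.db)]

    def forward(self, X: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        B, T, D = X.shape
        Hd = self.hidden
        h = np.zeros((B, Hd), dtype=DTYPE)
        c = np.zeros((B, Hd), dtype=DTYPE)
        H_seq = np.empty((B, T, Hd), dtype=DTYPE)
        cache = {"X": X, "z": [], "i": [], "f": [], "g": [], "o": [], "c": [], "tc": [], "c_prev": []}
        for t in range(T):
            z = np.concatenate([h, X[:, t]], axis=1)
            a = z @ self.W + self.b
            i = _sigmoid(a[:, :Hd])
            f = _sigmoid(a[:, Hd : 2 * Hd])
            g = np.tanh(a[:, 2 * Hd : 3 * Hd])
            o = _sigmoid(a[:, 3 * Hd :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            H_seq[:, t] = h
            if keep_cache:
                for key, val in zip(
                    ("z", "i", "f", "g", "o", "c", "tc", "c_prev"), (z, i, f, g, o, c, tc, c_prev)
                ):
                    cache[key].append(val)
        self._cache = cache if keep_cache else None
        return H_seq

    def backward(self, dH_seq: np.ndarray) -> np.ndarray:
        """Given d(loss)/d(H_seq), accumulate weight grads and return dX."""
        cache = self._cache
        assert cache is not None, "forward(keep_cache=True) must run before backward"
        X = cache["X"]
        B, T, D = X.shape
        Hd = self.hidden
        dX = np.zeros_like(X)
        self.dW[...] = 0.0
        self.db[...] = 0.0
        dh_next = np.zeros((B, Hd), dtype=DTYPE)
        dc_next = np.zeros((B, Hd), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            i, f, g, o = cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t]
            tc, c_prev, z = cache["tc"][t], cache["c_prev"][t], cache["z"][t]
            dh = dH_seq[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dA = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)], axis=1
            )
            self.dW += z.T @ dA
            self.db += dA.sum(axis=0)
            dz = dA @ self.W.T
            dh_next = dz[:, :Hd]
            dX[:, t] = dz[:, Hd:]
        return dX


class DropoutLayer(Layer):
    """Inverted dropout applied to a full sequence output."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, X: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
        if rng is None or self.rate == 0.0:  # eval mode
            self._mask = None
            return X
        self._mask = (rng.random(X.shape) >= self.rate).astype(DTYPE) / DTYPE(1.0 - self.rate)
        return X * self._mask

    def backward(self, dY: np.ndarray) -> np.ndarray:
        return dY if self._mask is None else dY * self._mask


class DenseLayer(Layer):
    def __init__(
        self, input_dim: int, units: int, activation: str, rng: np.random.Generator, name: str
    ):
        if activation not in ("relu", "linear", "exponential"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.activation = activation
        self.name = name
        self.W = _glorot(rng, input_dim, units, (input_dim, units))
        self.b = np.zeros(units, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def params(self):
        return [(f"{self.name}.W", self.W), (f"{self.name}.b", self.b)]

    def grads(self):
        return [(f"{self.name}.W", self.dW), (f"{self.name}.b", self.db)]

    def forward(self, X: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        a = X @ self.W + self.b
        if self.activation == "relu":
            y = np.maximum(a, 0.0)
        elif self.activation == "exponential":
            y = np.exp(np.minimum(a, 30.0))  # overflow guard
        else:
            y = a
        if keep_cache:
            self._cache = (X, a, y)
        return y

    def backward(self, dY: np.ndarray) -> np.ndarray:
        X, a, y = self._cache
        if self.activation == "relu":
            da = dY * (a > 0)
        elif self.activation == "exponential":
            da = dY * y
        else:
            da = dY
        self.dW[...] = X.T @ da
        self.db[...] = da.sum(axis=0)
        return da @ self.W.T


class Adam:
    """Adam optimizer over a fixed list of (name, param, grad) triples."""

    def __init__(self, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8, clip_norm: float = 5.0):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: list[tuple[str, np.ndarray]], grads: list[tuple[str, np.ndarray]]):
        gnorm = np.sqrt(sum(float((g * g).sum()) for _, g in grads))
        scale = DTYPE(min(1.0, self.clip_norm / (gnorm + 1e-12)))
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for (name, p), (_, g) in zip(params, grads):
            g = g * scale
            m = self.m.setdefault(name, np.zeros_like(p))
            v = self.v.setdefault(name, np.zeros_like(p))
            m[...] = self.beta1 * m + (1.0 - self.beta1) * g
            v[...] = self.beta2 * v + (1.0 - self.beta2) * g * g
            p -= DTYPE(self.lr) * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
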