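"""Minimal feed-forward / convolutional / recurrent layers with manual backprop.

All models in this package are small (feature dimension ~14, hidden widths
32-80), so a compact NumPy implementation with explicit reverse-mode
gradients is sufficient and keeps the whole pipeline dependency-light and
deterministic.  Layers cache what their backward pass needs; ``Sequential``
chains them and exposes flat parameter/gradient lists for the optimiser.

Conventions: inputs are ``(batch, features)`` float64 arrays, except for the
recurrent/convolutional layers which view a row as a length-``T`` sequence
with one channel.  Gradients returned by ``backward`` are with respect to the
layer input; parameter gradients accumulate into ``layer.grads``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "ReLU",
    "AsSequence",
    "Flatten",
    "Conv1D",
    "LSTM",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "mse_loss",
    "l1_loss",
]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: parameter-free layers override only forward/backward."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.w = _glorot(rng, (in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.grads[0] += self._x.T @ grad
        self.grads[1] += grad.sum(axis=0)
        return grad @ self.w.T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class AsSequence(Layer):
    """Reshape ``(batch, F)`` rows into ``(batch, F, 1)`` single-channel sequences."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x[:, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad[:, :, 0]


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Conv1D(Layer):
    """Valid-padding 1-D convolution, stride 1.

    Input ``(batch, T, C_in)`` -> output ``(batch, T - k + 1, C_out)``.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel = kernel
        limit = np.sqrt(6.0 / (kernel * in_channels + out_channels))
        self.w = rng.uniform(-limit, limit, size=(kernel, in_channels, out_channels))
        self.b = np.zeros(out_channels)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        t_out = x.shape[1] - self.kernel + 1
        out = np.zeros((x.shape[0], t_out, self.w.shape[2]))
        for j in range(self.kernel):
            out += np.einsum("btc,cf->btf", x[:, j:j + t_out, :], self.w[j])
        return out + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        t_out = grad.shape[1]
        dx = np.zeros_like(x)
        for j in range(self.kernel):
            self.grads[0][j] += np.einsum("btc,btf->cf", x[:, j:j + t_out, :], grad)
            dx[:, j:j + t_out, :] += np.einsum("btf,cf->btc", grad, self.w[j])
        self.grads[1] += grad.sum(axis=(0, 1))
        return dx


class LSTM(Layer):
    """Single LSTM layer with optional full-sequence output.

    Input ``(batch, T, C_in)``; output ``(batch, T, H)`` when
    ``return_sequences`` else the final hidden state ``(batch, H)``.
    Gate order in the stacked weight matrices: input, forget, cell, output.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator,
                 return_sequences: bool = False) -> None:
        super().__init__()
        self.hidden = hidden
        self.return_sequences = return_sequences
        self.wx = _glorot(rng, (in_dim, 4 * hidden))
        self.wh = _glorot(rng, (hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        # forget-gate bias of 1 is the standard initialisation for trainability
        self.b[hidden:2 * hidden] = 1.0
        self.params = [self.wx, self.wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    @staticmethod
    def _sigmoid(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, t, _ = x.shape
        h = self.hidden
        self._x = x
        self._cache = []
        hs = np.zeros((b, t, h))
        h_prev = np.zeros((b, h))
        c_prev = np.zeros((b, h))
        for step in range(t):
            gates = x[:, step, :] @ self.wx + h_prev @ self.wh + self.b
            i = self._sigmoid(gates[:, :h])
            f = self._sigmoid(gates[:, h:2 * h])
            g = np.tanh(gates[:, 2 * h:3 * h])
            o = self._sigmoid(gates[:, 3 * h:])
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_new = o * tc
            self._cache.append((h_prev, c_prev, i, f, g, o, c, tc))
            hs[:, step, :] = h_new
            h_prev, c_prev = h_new, c
        self._hs = hs
        return hs if self.return_sequences else h_prev

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        b, t, _ = x.shape
        h = self.hidden
        dx = np.zeros_like(x)
        dh_next = np.zeros((b, h))
        dc_next = np.zeros((b, h))
        if self.return_sequences:
            seq_grad = grad
        else:
            seq_grad = np.zeros((b, t, h))
            seq_grad[:, -1, :] = grad
        for step in range(t - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c, tc = self._cache[step]
            dh = seq_grad[:, step, :] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dgates = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2), do * o * (1 - o)],
                axis=1,
            )
            self.grads[0] += x[:, step, :].T @ dgates
            self.grads[1] += h_prev.T @ dgates
            self.grads[2] += dgates.sum(axis=0)
            dx[:, step, :] = dgates @ self.wx.T
            dh_next = dgates @ self.wh.T
            dc_next = dc * f
        return dx


class Sequential:
    """Plain layer chain with shared parameter bookkeeping."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def param_bytes(self) -> bytes:
        """Canonical serialisation of all parameters, for identity checks."""
        return b"".join(np.ascontiguousarray(p).tobytes() for p in self.params)

    def set_params(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self.params, values, strict=True):
            p[...] = v


class Adam:
    """Adaptive-moment optimiser over an explicit parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer ``labels``; returns (loss, dloss/dlogits)."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size
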