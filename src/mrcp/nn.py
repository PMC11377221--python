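"""Minimal deterministic CNN engine in numpy.

Conv2D (3x3, same padding) / ReLU / MaxPool / Dense layers with explicit
backprop and an Adam optimizer. Everything is float32 and single-threaded
numpy, so a fixed seed gives bit-identical training runs on the same
platform. Layers carry a ``trainable`` flag; the optimizer never touches a
frozen layer's parameters.

Array layout is (N, C, H, W): batch, feature maps, spatial rows (EEG
channels), spatial columns (time samples).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Layer:
    """Base layer: params/grads dicts and a trainable flag."""

    trainable: bool = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


def _im2col3x3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patch matrix for 3x3 same-padding conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)


class Conv2D(Layer):
    """3x3 convolution, stride 1, same (zero) padding, He-initialized."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / (c_in * 9))
        self.params["W"] = (scale * rng.standard_normal((c_out, c_in * 9))).astype(DTYPE)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        n, c, h, w = x.shape
        self._cols = _im2col3x3(x)
        y = self._cols @ self.params["W"].T + self.params["b"]
        return y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dy = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.grads["W"] = (dy.T @ self._cols).astype(DTYPE)
        self.grads["b"] = dy.sum(axis=0).astype(DTYPE)
        # dx = same-padding conv of dout with the spatially flipped,
        # channel-transposed kernel
        W = self.params["W"].reshape(self.c_out, self.c_in, 3, 3)
        W_flip = W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.c_in, self.c_out * 9)
        cols_dy = _im2col3x3(dout)
        dx = cols_dy @ W_flip.T
        self._cols = None
        return dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)


class ReLU(Layer):
    trainable = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool(Layer):
    """Non-overlapping max pooling with pool shape (ph, pw); odd remainders
    on either axis are cropped (standard floor behavior)."""

    trainable = False

    def __init__(self, ph: int, pw: int) -> None:
        super().__init__()
        self.ph, self.pw = ph, pw

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // self.ph, w // self.pw
        self._in_shape = x.shape
        xc = x[:, :, : h2 * self.ph, : w2 * self.pw]
        xr = xc.reshape(n, c, h2, self.ph, w2, self.pw).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h2, w2, self.ph * self.pw)
        self._argmax = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        h2, w2 = h // self.ph, w // self.pw
        dxr = np.zeros((n, c, h2, w2, self.ph * self.pw), dtype=dout.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=-1)
        dxc = dxr.reshape(n, c, h2, w2, self.ph, self.pw).transpose(0, 1, 2, 4, 3, 5)
        dxc = dxc.reshape(n, c, h2 * self.ph, w2 * self.pw)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, :, : h2 * self.ph, : w2 * self.pw] = dxc
        return dx


class Dropout(Layer):
    """Inverted dropout on the fully connected block (train mode only).

    Uses its own seeded generator so training remains deterministic.
    """

    trainable = False

    def __init__(self, rate: float, seed: int = 0) -> None:
        super().__init__()
        self.rate = rate
        self.rng = np.random.default_rng(seed)
        self.training = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    trainable = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        scale = np.sqrt(2.0 / n_in)
        self.params["W"] = (scale * rng.standard_normal((n_in, n_out))).astype(DTYPE)
        self.params["b"] = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = (self._x.T @ dout).astype(DTYPE)
        self.grads["b"] = dout.sum(axis=0).astype(DTYPE)
        dx = dout @ self.params["W"].T
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent_from_logits(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.mean(np.log(np.clip(p[np.arange(n), y], 1e-12, None)))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), (dlogits / n).astype(DTYPE)


class Sequential:
    """Plain layer stack with forward/backward passes."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def parametrized(self) -> list[Layer]:
        return [l for l in self.layers if l.params]


class Adam:
    """Adam optimizer; skips layers whose ``trainable`` flag is False."""

    def __init__(self, model: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0) -> None:
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.state: dict[int, dict[str, tuple[np.ndarray, np.ndarray]]] = {}

    def step(self) -> None:
        self.t += 1
        for i, layer in enumerate(self.model.layers):
            if not layer.params or not layer.trainable:
                continue
            st = self.state.setdefault(i, {})
            for name, p in layer.params.items():
                g = layer.grads[name]
                m, v = st.get(name, (np.zeros_like(p), np.zeros_like(p)))
                m = self.beta1 * m + (1 - self.beta1) * g
                v = self.beta2 * v + (1 - self.beta2) * g * g
                st[name] = (m, v)
                mhat = m / (1 - self.beta1**self.t)
                vhat = v / (1 - self.beta2**self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
                if self.weight_decay and name == "W":  # decoupled, weights only
                    p -= (self.lr * self.weight_decay * p).astype(DTYPE)
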