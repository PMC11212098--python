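"""Minimal CPU neural-network engine: layers, backprop and Adam.

The grading model needs only a small set of primitives — 2D convolution,
batch normalization, ReLU, max/global-average pooling, linear maps, residual
composition, softmax cross-entropy and Adam with L2 weight decay — so they
are implemented here directly on numpy arrays.  Layers are stateful: each
``forward`` caches what its ``backward`` needs, which is safe in the
single-threaded training loop used throughout.  All computation is float64
free of BLAS-threading nondeterminism sources beyond numpy's own, so a fixed
seed reproduces training bit-for-bit in single-threaded mode.

Data layout is channel-first: images are (N, C, H, W).
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError


class Layer:
    """Base layer: parameter/gradient registries plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def set_training(self, flag: bool) -> None:
        self.training = flag

    def named_params(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        return [(prefix + k, v) for k, v in self.params.items()]

    def named_grads(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        return [(prefix + k, v) for k, v in self.grads.items()]

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        """Non-trainable state (e.g. batch-norm running stats)."""
        return []


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    hp = (h + 2 * pad - k) // stride + 1
    wp = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]          # (N, C, hp, wp, k, k)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * hp * wp, c * k * k)
    return np.ascontiguousarray(cols), hp, wp


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int,
            hp: int, wp: int) -> np.ndarray:
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d6 = dcols.reshape(n, hp, wp, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * hp:stride, j:j + stride * wp:stride] += d6[:, :, :, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Layer):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        self.k, self.stride, self.pad = kernel_size, stride, padding
        self.in_channels, self.out_channels = in_channels, out_channels
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      (out_channels, fan_in)).astype(np.float32)
        if bias:
            self.params["b"] = np.zeros(out_channels, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValidationError(
                f"Conv2d expected {self.in_channels} channels, got {x.shape[1]}")
        cols, hp, wp = _im2col(x, self.k, self.stride, self.pad)
        out = cols @ self.params["W"].T
        if "b" in self.params:
            out = out + self.params["b"]
        n = x.shape[0]
        self._cache = (x.shape, cols, hp, wp)
        return out.reshape(n, hp, wp, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, cols, hp, wp = self._cache
        n = x_shape[0]
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * hp * wp, self.out_channels)
        self.grads["W"] = (dflat.T @ cols).astype(np.float32)
        if "b" in self.params:
            self.grads["b"] = dflat.sum(axis=0).astype(np.float32)
        dcols = dflat @ self.params["W"]
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, hp, wp)


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean *= self.momentum
            self.running_mean += (1 - self.momentum) * mean
            self.running_var *= self.momentum
            self.running_var += (1 - self.momentum) * var
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        mean = np.asarray(mean, dtype=x.dtype)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return (self.params["gamma"][None, :, None, None] * xhat
                + self.params["beta"][None, :, None, None])

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        return [(prefix + "running_mean", self.running_mean),
                (prefix + "running_var", self.running_var)]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n, _, h, w = dout.shape
        m = n * h * w
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3)).astype(np.float32)
        self.grads["beta"] = dout.sum(axis=(0, 2, 3)).astype(np.float32)
        g = self.params["gamma"][None, :, None, None]
        dxhat = dout * g
        dx = (inv_std[None, :, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True))
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2d(Layer):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0) -> None:
        super().__init__()
        self.k, self.stride, self.pad = kernel_size, stride, padding

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)),
                    constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, ::self.stride, ::self.stride]
        hp, wp = win.shape[2], win.shape[3]
        flat = win.reshape(n, c, hp, wp, self.k * self.k)
        self._argmax = flat.argmax(axis=4)
        self._x_shape, self._hp, self._wp = x.shape, hp, wp
        return flat.max(axis=4)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        hp, wp = self._hp, self._wp
        dxp = np.zeros((n, c, h + 2 * self.pad, w + 2 * self.pad), dtype=dout.dtype)
        ki = self._argmax // self.k
        kj = self._argmax % self.k
        ni, ci, hi, wi = np.indices((n, c, hp, wp))
        rows = hi * self.stride + ki
        cols = wi * self.stride + kj
        np.add.at(dxp, (ni, ci, rows, cols), dout)
        if self.pad:
            return dxp[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return dxp


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_features, self.out_features = in_features, out_features
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / in_features),
                                      (out_features, in_features)).astype(np.float32)
        self.params["b"] = np.zeros(out_features, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_features:
            raise ValidationError(
                f"Linear expected {self.in_features} features, got {x.shape[1]}")
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = (dout.T @ self._x).astype(np.float32)
        self.grads["b"] = dout.sum(axis=0).astype(np.float32)
        return dout @ self.params["W"]


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for layer in self.layers:
            layer.set_training(flag)

    def named_params(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = []
        for i, layer in enumerate(self.layers):
            out.extend(layer.named_params(f"{prefix}{i}."))
        return out

    def named_grads(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = []
        for i, layer in enumerate(self.layers):
            out.extend(layer.named_grads(f"{prefix}{i}."))
        return out

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = []
        for i, layer in enumerate(self.layers):
            out.extend(layer.named_buffers(f"{prefix}{i}."))
        return out


class Residual(Layer):
    """y = main(x) + shortcut(x), followed by ReLU."""

    def __init__(self, main: Sequential, shortcut: Layer | None = None) -> None:
        super().__init__()
        self.main = main
        self.shortcut = shortcut
        self.relu = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.main.forward(x)
        s = self.shortcut.forward(x) if self.shortcut is not None else x
        return self.relu.forward(y + s)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu.backward(dout)
        dx_main = self.main.backward(d)
        dx_short = self.shortcut.backward(d) if self.shortcut is not None else d
        return dx_main + dx_short

    def set_training(self, flag: bool) -> None:
        self.training = flag
        self.main.set_training(flag)
        if self.shortcut is not None:
            self.shortcut.set_training(flag)

    def named_params(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = self.main.named_params(prefix + "main.")
        if self.shortcut is not None:
            out += self.shortcut.named_params(prefix + "short.")
        return out

    def named_grads(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = self.main.named_grads(prefix + "main.")
        if self.shortcut is not None:
            out += self.shortcut.named_grads(prefix + "short.")
        return out

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = self.main.named_buffers(prefix + "main.")
        if self.shortcut is not None:
            out += self.shortcut.named_buffers(prefix + "short.")
        return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and the gradient w.r.t. the *logits*.

    ``targets`` are integer class indices.  With softmax outputs the logit
    gradient is (p - onehot)/N.
    """
    n = probs.shape[0]
    eps = 1e-12
    loss = float(-np.log(probs[np.arange(n), targets] + eps).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adam with decoupled-from-loss L2 weight decay added to the gradient."""

    def __init__(self, learning_rate: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.99, weight_decay: float = 5e-4,
                 eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2 = learning_rate, beta1, beta2
        self.weight_decay, self.eps = weight_decay, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, named_params: list[tuple[str, np.ndarray]],
             named_grads: list[tuple[str, np.ndarray]]) -> None:
        grads = dict(named_grads)
        self.t += 1
        for name, p in named_params:
            g = grads[name].astype(np.float64)
            if self.weight_decay and not name.endswith(("beta", "gamma", ".b")):
                g = g + self.weight_decay * p
            m = self.m.setdefault(name, np.zeros_like(g))
            v = self.v.setdefault(name, np.zeros_like(g))
            m[:] = self.beta1 * m + (1 - self.beta1) * g
            v[:] = self.beta2 * v + (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1 ** self.t)
            vhat = v / (1 - self.beta2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
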