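"""Layers with explicit forward/backward passes (float32, CPU).

Convolutions are expressed as im2col + matrix multiply so the heavy
lifting happens in BLAS. Each layer caches what its backward pass needs
and releases it afterwards.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from ..errors import ParameterError

F32 = np.float32


def _im2col3x3(x: np.ndarray) -> np.ndarray:
    """[N,C,H,W] -> [N*H*W, C*9] patches of the zero-padded input."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    s0, s1, s2, s3 = xp.strides
    view = as_strided(xp, shape=(n, c, h, w, 3, 3), strides=(s0, s1, s2, s3, s2, s3))
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)


class Layer:
    """Base layer: parameters live in ``params``/``grads`` dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k, g in self.grads.items():
            g[...] = 0.0


class Conv2d(Layer):
    """3x3 same-padding convolution (stride 1)."""

    kernel_size = 3

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * 9
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_channels))
        self.params = {"W": w.astype(F32), "b": np.zeros(out_channels, dtype=F32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._col: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ParameterError(f"expected {self.in_channels} input channels, got {c}")
        col = _im2col3x3(x)
        self._col, self._shape = col, x.shape
        y = col @ self.params["W"] + self.params["b"]
        return y.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, _, h, w = self._shape
        dy_flat = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_channels)
        self.grads["W"] += self._col.T @ dy_flat
        self.grads["b"] += dy_flat.sum(axis=0)
        self._col = None
        # dx = dy convolved with the 180deg-rotated kernels, channels swapped
        w_rot = (self.params["W"]
                 .reshape(self.in_channels, 3, 3, self.out_channels)[:, ::-1, ::-1, :]
                 .transpose(3, 1, 2, 0)
                 .reshape(self.out_channels * 9, self.in_channels))
        dcol = _im2col3x3(dy)
        dx = dcol @ w_rot
        return dx.reshape(n, h, w, self.in_channels).transpose(0, 3, 1, 2)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(F32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; gradient routed to the first maximum."""

    def __init__(self) -> None:
        super().__init__()
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ParameterError(f"spatial size {h}x{w} not divisible by 2")
        hh, wh = h // 2, w // 2
        xr = (x.reshape(n, c, hh, 2, wh, 2)
               .transpose(0, 1, 2, 4, 3, 5)
               .reshape(n, c, hh, wh, 4))
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        hh, wh = h // 2, w // 2
        dxr = np.zeros((n, c, hh, wh, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        self._idx = None
        return (dxr.reshape(n, c, hh, wh, 2, 2)
                   .transpose(0, 1, 2, 4, 3, 5)
                   .reshape(n, c, h, w))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class SEBlock(Layer):
    """Squeeze-and-excitation channel gate.

    Squeeze: per-channel spatial mean. Excitation: two-layer gate,
    ReLU inner, sigmoid outer, hidden width ``max(1, C // reduction)``.
    Scale: per-channel scalar in (0, 1) multiplies the input map, so the
    output magnitude never exceeds the input's.

    ``force_identity=True`` bypasses the gate (as if every scale were 1),
    which turns the surrounding network into its plain-VGG ablation.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        if reduction < 1:
            raise ParameterError("reduction must be >= 1")
        self.channels = channels
        self.reduction = reduction
        hidden = max(1, channels // reduction)
        self.hidden = hidden
        self.params = {
            "W1": rng.normal(0.0, np.sqrt(2.0 / channels), size=(channels, hidden)).astype(F32),
            "b1": np.zeros(hidden, dtype=F32),
            "W2": rng.normal(0.0, np.sqrt(2.0 / hidden), size=(hidden, channels)).astype(F32),
            "b2": np.zeros(channels, dtype=F32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.force_identity = False
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ParameterError(f"expected {self.channels} channels, got {x.shape[1]}")
        if self.force_identity:
            self._cache = None
            return x
        z = x.mean(axis=(2, 3))
        h_pre = z @ self.params["W1"] + self.params["b1"]
        h = np.maximum(h_pre, 0.0)
        s = _sigmoid(h @ self.params["W2"] + self.params["b2"])
        self._cache = (x, z, h_pre, h, s)
        return x * s[:, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.force_identity:
            return dy
        x, z, h_pre, h, s = self._cache
        self._cache = None
        hw = x.shape[2] * x.shape[3]
        dx = dy * s[:, :, None, None]
        ds = (dy * x).sum(axis=(2, 3))
        ds_pre = ds * s * (1.0 - s)
        self.grads["W2"] += h.T @ ds_pre
        self.grads["b2"] += ds_pre.sum(axis=0)
        dh = (ds_pre @ self.params["W2"].T) * (h_pre > 0)
        self.grads["W1"] += z.T @ dh
        self.grads["b1"] += dh.sum(axis=0)
        dz = dh @ self.params["W1"].T
        dx += dz[:, :, None, None] / hw
        return dx


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.params = {"W": w.astype(F32), "b": np.zeros(out_features, dtype=F32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        dx = dy @ self.params["W"].T
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.maximum(p[np.arange(n), labels], 1e-30)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(F32)


class Network:
    """A plain sequential network."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.ascontiguousarray(x, dtype=F32)
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        grad = dy
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities (rows sum to 1); deterministic in eval."""
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(softmax(self.forward(x[i:i + batch_size]).astype(np.float64)))
        return np.concatenate(outs, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    # -- parameter plumbing -------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                state[f"{i}.{k}"] = v.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k][...] = state[f"{i}.{k}"]

    def n_parameters(self) -> int:
        return sum(v.size for layer in self.layers for v in layer.params.values())


class SGD:
    """Stochastic gradient descent with optional classical momentum and
    L2 weight decay (applied to weight matrices, not biases)."""

    def __init__(self, network: Network, learning_rate: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        if learning_rate < 0:
            raise ParameterError("learning_rate must be >= 0")
        self.network = network
        self.lr = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        for i, layer in enumerate(self.network.layers):
            for k, w in layer.params.items():
                g = layer.grads[k]
                if self.weight_decay > 0 and not k.startswith("b"):
                    g = g + self.weight_decay * w
                if self.momentum > 0:
                    v = self._velocity.setdefault((i, k), np.zeros_like(w))
                    v *= self.momentum
                    v -= self.lr * g
                    w += v
                else:
                    w -= self.lr * g
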