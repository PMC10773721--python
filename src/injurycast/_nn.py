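"""Minimal feed-forward / convolutional network core used by the models.

Implements exactly the pieces the architecture needs — dense and 3x3
same-padding convolution layers, 2x2 max pooling and nearest-neighbour
upsampling, batch normalization, dropout, SELU/tanh/sigmoid activations, and
an adadelta optimizer — with reverse-mode gradients, on plain numpy arrays in
NHWC layout.  Training is deterministic for a fixed Generator.
"""

from __future__ import annotations

import numpy as np

_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    """Base layer: forward caches whatever backward needs."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # LeCun-normal init, appropriate for SELU networks
        self.W = Param(rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class Conv2D(Layer):
    """3x3 convolution with stride 1 and same padding, NHWC."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, kernel: int = 3):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k = kernel
        fan_in = kernel * kernel * c_in
        self.W = Param(rng.normal(0.0, 1.0 / np.sqrt(fan_in),
                                  size=(kernel * kernel * c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.c_in, self.c_out = c_in, c_out

    def _im2col(self, x):
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        # (N, H, W, C, k, k) -> (N, H, W, k, k, C)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
        return cols

    def forward(self, x, training, rng):
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        self._shape = x.shape
        cols = self._im2col(x).reshape(n * h * w, -1)
        self._cols = cols
        out = cols @ self.W.value + self.b.value
        return out.reshape(n, h, w, self.c_out)

    def backward(self, grad):
        n, h, w, _ = self._shape
        g = grad.reshape(n * h * w, self.c_out)
        self.W.grad += self._cols.T @ g
        self.b.grad += g.sum(axis=0)
        dcols = (g @ self.W.value.T).reshape(n, h, w, self.k, self.k, self.c_in)
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.c_in))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p : p + h, p : p + w, :]

    def params(self):
        return [self.W, self.b]


class MaxPool2(Layer):
    def forward(self, x, training, rng):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        mask = xr == out[:, :, None, :, None, :]
        self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)  # split ties
        self._shape = x.shape
        return out

    def backward(self, grad):
        g = grad[:, :, None, :, None, :] * self._mask
        return g.reshape(self._shape)


class Upsample2(Layer):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x, training, rng):
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, grad):
        n, h, w, c = grad.shape
        return grad.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class BatchNorm(Layer):
    """Per-channel batch normalization over all leading axes.

    Placed after the affine transform, before the activation.  Inference uses
    exponential running statistics.
    """

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_channels))
        self.beta = Param(np.zeros(n_channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training, rng):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._axes = axes
        self._m = int(np.prod([x.shape[a] for a in axes])) if training else 0
        self._training = training
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad):
        axes = self._axes
        self.gamma.grad += (grad * self._xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        if not self._training:
            return grad * self.gamma.value / self._std
        m = self._m
        g = grad * self.gamma.value
        return (g - g.mean(axis=axes)
                - self._xhat * (g * self._xhat).sum(axis=axes) / m) / self._std


class Dropout(Layer):
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.uniform(size=x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Activation(Layer):
    def __init__(self, kind: str):
        if kind not in ("selu", "tanh", "sigmoid", "linear"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x, training, rng):
        if self.kind == "selu":
            self._x = x
            return _SELU_LAMBDA * np.where(x > 0, x, _SELU_ALPHA * (np.exp(np.minimum(x, 0)) - 1))
        if self.kind == "tanh":
            self._y = np.tanh(x)
            return self._y
        if self.kind == "sigmoid":
            self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
            return self._y
        return x

    def backward(self, grad):
        if self.kind == "selu":
            x = self._x
            d = _SELU_LAMBDA * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(x, 0)))
            return grad * d
        if self.kind == "tanh":
            return grad * (1.0 - self._y**2)
        if self.kind == "sigmoid":
            return grad * self._y * (1.0 - self._y)
        return grad


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        self.shape = shape

    def forward(self, x, training, rng):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Flatten(Reshape):
    def __init__(self):
        pass

    def forward(self, x, training, rng):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training, rng):
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict(self, x, batch_size: int = 4096) -> np.ndarray:
        """Inference-mode forward in batches (dropout off, BN running stats)."""
        rng = np.random.default_rng(0)  # unused in inference
        outs = [self.forward(x[i : i + batch_size], False, rng)
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs) if outs else np.empty((0,))

    def get_weights(self) -> list[np.ndarray]:
        arrays = [p.value for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                arrays += [layer.running_mean, layer.running_var]
        return arrays

    def set_weights(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for p in self.params():
            p.value = next(it).copy()
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()


class Adadelta:
    """Adadelta: adaptive per-parameter steps, initial step 1.0, decay rho."""

    def __init__(self, params: list[Param], lr: float = 1.0, rho: float = 0.95,
                 eps: float = 1e-6):
        self.params = params
        self.lr, self.rho, self.eps = lr, rho, eps
        self.Eg2 = [np.zeros_like(p.value) for p in params]
        self.Edx2 = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p, eg2, edx2 in zip(self.params, self.Eg2, self.Edx2):
            g = p.grad
            eg2 *= self.rho
            eg2 += (1 - self.rho) * g * g
            dx = -np.sqrt(edx2 + self.eps) / np.sqrt(eg2 + self.eps) * g
            edx2 *= self.rho
            edx2 += (1 - self.rho) * dx * dx
            p.value += self.lr * dx
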