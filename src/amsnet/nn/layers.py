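"""Layers with hand-written backward passes.

Conventions
-----------
* Activations are ``float64`` arrays shaped ``(N, C, H, W)`` (or ``(N, F)``
  for fully connected layers).
* ``forward(x, training)`` returns the output; with ``training=True`` the
  layer caches whatever ``backward`` needs.
* ``backward(grad_out)`` returns ``grad_in`` and adds parameter gradients to
  ``self.grads`` (zeroed by the optimizer between steps).
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class Module:
    """Base class: parameter store plus child traversal."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        super().__setattr__(name, value)

    def add_param(self, name: str, value: np.ndarray) -> None:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)

    def modules(self):
        yield self
        for child in self._children.values():
            yield from child.modules()

    def named_parameters(self, prefix: str = ""):
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")
        for pname in self.params:
            yield prefix + pname, self, pname

    def n_parameters(self) -> int:
        return sum(m.params[k].size for _, m, k in self.named_parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: m.params[k].copy() for name, m, k in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {name: (m, k) for name, m, k in self.named_parameters()}
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, (m, k) in own.items():
            if state[name].shape != m.params[k].shape:
                raise ValueError(f"shape mismatch for {name}")
            m.params[k] = state[name].copy()
            m.grads[k] = np.zeros_like(m.params[k])

    # buffers (batch-norm running stats) ride along with the state dict
    def buffers_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, mod in enumerate(self.modules()):
            if isinstance(mod, BatchNorm2d):
                out[f"bn{i}.running_mean"] = mod.running_mean.copy()
                out[f"bn{i}.running_var"] = mod.running_var.copy()
        return out

    def load_buffers_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, mod in enumerate(self.modules()):
            if isinstance(mod, BatchNorm2d):
                mod.running_mean = state[f"bn{i}.running_mean"].copy()
                mod.running_var = state[f"bn{i}.running_var"].copy()

    def forward(self, x, training=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x, training=False):
        return self.forward(x, training=training)


def _out_size(size: int, k: int, stride: int, pad: int, dil: int) -> int:
    eff = dil * (k - 1) + 1
    return (size + 2 * pad - eff) // stride + 1


def im2col(x: np.ndarray, k: int, stride: int, pad: int, dil: int,
           pad_value: float = 0.0) -> np.ndarray:
    """Unfold ``(N,C,H,W)`` into ``(N, C, k, k, Ho, Wo)`` patch tensor."""
    n, c, h, w = x.shape
    ho = _out_size(h, k, stride, pad, dil)
    wo = _out_size(w, k, stride, pad, dil)
    if ho <= 0 or wo <= 0:
        raise ValueError("kernel larger than padded input")
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                constant_values=pad_value) if pad else x
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            i0, j0 = i * dil, j * dil
            cols[:, :, i, j] = xp[:, :, i0:i0 + stride * ho:stride,
                                  j0:j0 + stride * wo:stride]
    return cols


def col2im(dcols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int,
           dil: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patches back onto the image."""
    n, c, h, w = x_shape
    _, _, _, _, ho, wo = dcols.shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            i0, j0 = i * dil, j * dil
            dxp[:, :, i0:i0 + stride * ho:stride,
                j0:j0 + stride * wo:stride] += dcols[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp


class Conv2d(Module):
    """2-D convolution (cross-correlation) with stride, padding and dilation."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        # He-normal initialization, appropriate for the ReLU trunk
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels, kernel_size, kernel_size))
        self.add_param("weight", w)
        self.use_bias = bias
        if bias:
            self.add_param("bias", np.zeros(out_channels))
        self._cache = None

    def forward(self, x, training=False):
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (N,{self.in_channels},H,W) input, got {x.shape}")
        n = x.shape[0]
        cols = im2col(x, self.k, self.stride, self.padding, self.dilation)
        ho, wo = cols.shape[-2:]
        flat = cols.reshape(n, self.in_channels * self.k * self.k, ho * wo)
        wmat = self.params["weight"].reshape(self.out_channels, -1)
        y = np.matmul(wmat, flat).reshape(n, self.out_channels, ho, wo)
        if self.use_bias:
            y += self.params["bias"][None, :, None, None]
        if training:
            self._cache = (x.shape, flat, ho, wo)
        return y

    def backward(self, grad):
        x_shape, flat, ho, wo = self._cache
        n = grad.shape[0]
        g = grad.reshape(n, self.out_channels, ho * wo)
        wmat = self.params["weight"].reshape(self.out_channels, -1)
        self.grads["weight"] += np.matmul(
            g, flat.transpose(0, 2, 1)).sum(axis=0).reshape(self.params["weight"].shape)
        if self.use_bias:
            self.grads["bias"] += g.sum(axis=(0, 2))
        dflat = np.matmul(wmat.T, g)
        dcols = dflat.reshape(n, self.in_channels, self.k, self.k, ho, wo)
        return col2im(dcols, x_shape, self.k, self.stride, self.padding,
                      self.dilation)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.add_param("gamma", np.ones(channels))
        self.add_param("beta", np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean \
                + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var \
                + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        y = self.params["gamma"][None, :, None, None] * xhat \
            + self.params["beta"][None, :, None, None]
        if training:
            self._cache = (xhat, inv_std)
        return y

    def backward(self, grad):
        xhat, inv_std = self._cache
        n, _, h, w = grad.shape
        m = n * h * w
        self.grads["gamma"] += (grad * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += grad.sum(axis=(0, 2, 3))
        g = grad * self.params["gamma"][None, :, None, None]
        sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (g - sum_g / m - xhat * sum_gx / m) \
            * inv_std[None, :, None, None]
        return dx


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng(0)
        self.add_param("weight", rng.normal(
            0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features)))
        self.use_bias = bias
        if bias:
            self.add_param("bias", np.zeros(out_features))
        self._cache = None

    def forward(self, x, training=False):
        if x.shape[-1] != self.in_features:
            raise ValueError(
                f"expected last dim {self.in_features}, got {x.shape}")
        y = x @ self.params["weight"].T
        if self.use_bias:
            y += self.params["bias"]
        if training:
            self._cache = x
        return y

    def backward(self, grad):
        x = self._cache
        self.grads["weight"] += grad.T @ x
        if self.use_bias:
            self.grads["bias"] += grad.sum(axis=0)
        return grad @ self.params["weight"]


class ReLU(Module):
    def forward(self, x, training=False):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Module):
    def forward(self, x, training=False):
        y = sigmoid(x)
        if training:
            self._y = y
        return y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.k, self.stride, self.padding = kernel_size, stride, padding
        self._cache = None

    def forward(self, x, training=False):
        cols = im2col(x, self.k, self.stride, self.padding, 1,
                      pad_value=-np.inf)
        n, c, _, _, ho, wo = cols.shape
        flat = cols.reshape(n, c, self.k * self.k, ho, wo)
        idx = flat.argmax(axis=2)
        y = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]
        if training:
            self._cache = (x.shape, idx, ho, wo)
        return y

    def backward(self, grad):
        x_shape, idx, ho, wo = self._cache
        n, c = x_shape[:2]
        dflat = np.zeros((n, c, self.k * self.k, ho, wo), dtype=grad.dtype)
        np.put_along_axis(dflat, idx[:, :, None], grad[:, :, None], axis=2)
        dcols = dflat.reshape(n, c, self.k, self.k, ho, wo)
        return col2im(dcols, x_shape, self.k, self.stride, self.padding, 1)


class GlobalAvgPool2d(Module):
    """(N,C,H,W) -> (N,C); keeps spatial extent for the backward pass."""

    def forward(self, x, training=False):
        if x.shape[2] == 0 or x.shape[3] == 0:
            raise ValueError("empty spatial extent")
        if training:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w),
                               (n, c, h, w)).copy()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._children[f"layer{i}"] = layer

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
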