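"""Minimal 3D convolutional-network layers in numpy, with exact backprop.

Provides exactly the primitives the dual-head segmentation U-Net needs —
3D convolution (stride 1, 'same' padding), batch normalization, ReLU,
2x max pooling, nearest-neighbor upsampling and SGD with momentum — with
forward/backward passes written against BLAS-backed tensor contractions.
Gradients are verified against central finite differences in the test
suite.

Tensors are laid out ``(batch, channels, x, y, z)``.  Layers cache what
backward needs; call ``forward`` then ``backward`` in matching order.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "ConvBlock",
    "SGD",
]


def _offsets(k: int):
    return [(a, b, c) for a in range(k) for b in range(k) for c in range(k)]


class Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """k^3 convolution, stride 1, zero padding k//2 (spatial shape preserved)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cin = in_channels
        self.cout = out_channels
        self.k = kernel_size
        self.pad = kernel_size // 2
        fan_in = in_channels * kernel_size**3
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.params["W"] = (
            rng.standard_normal((out_channels, in_channels, *(kernel_size,) * 3)) * scale
        ).astype(dtype)
        self.params["b"] = np.zeros(out_channels, dtype=dtype)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, X, Y, Z = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        self._xp = xp
        self._spatial = (X, Y, Z)
        W = self.params["W"]
        out = np.empty((self.cout, B, X, Y, Z), dtype=x.dtype)
        out[:] = self.params["b"].reshape(-1, 1, 1, 1, 1)
        for a, b, c in _offsets(self.k):
            xs = xp[:, :, a : a + X, b : b + Y, c : c + Z]
            out += np.tensordot(W[:, :, a, b, c], xs, axes=([1], [1]))
        return np.ascontiguousarray(np.moveaxis(out, 0, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        X, Y, Z = self._spatial
        dyT = np.moveaxis(dy, 1, 0)  # (O, B, X, Y, Z)
        W = self.params["W"]
        dxp = np.zeros_like(self._xp)
        for a, b, c in _offsets(self.k):
            xs = self._xp[:, :, a : a + X, b : b + Y, c : c + Z]
            self.grads["W"][:, :, a, b, c] = np.tensordot(
                dyT, xs, axes=([1, 2, 3, 4], [0, 2, 3, 4])
            )
            dxs = np.tensordot(W[:, :, a, b, c], dyT, axes=([0], [0]))  # (I, B, ...)
            dxp[:, :, a : a + X, b : b + Y, c : c + Z] += np.moveaxis(dxs, 0, 1)
        self.grads["b"][:] = dy.sum(axis=(0, 2, 3, 4))
        p = self.pad
        self._xp = None
        return dxp[:, :, p : p + X, p : p + Y, p : p + Z] if p else dxp


class BatchNorm3d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean.astype(np.float64) - self.running_mean)
            self.running_var += self.momentum * (var.astype(np.float64) - self.running_var)
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        shape = (1, -1, 1, 1, 1)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * invstd.reshape(shape)
        self._xhat = xhat if train else None
        self._invstd = invstd
        return self.params["gamma"].reshape(shape) * xhat + self.params["beta"].reshape(shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        xhat = self._xhat
        n = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        self.grads["gamma"][:] = (dy * xhat).sum(axis=axes)
        self.grads["beta"][:] = dy.sum(axis=axes)
        dxhat = dy * self.params["gamma"].reshape(shape)
        mean_dxhat = dxhat.mean(axis=axes).reshape(shape)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes).reshape(shape)
        dx = self._invstd.reshape(shape) * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
        self._xhat = None
        return dx.astype(dy.dtype)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = dy * self._mask
        self._mask = None
        return out


class MaxPool2(Layer):
    """2x2x2 max pooling; ties share the gradient equally (deterministic)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, X, Y, Z = x.shape
        if X % 2 or Y % 2 or Z % 2:
            raise ValueError("MaxPool2 requires even spatial dimensions")
        xr = x.reshape(B, C, X // 2, 2, Y // 2, 2, Z // 2, 2)
        y = xr.max(axis=(3, 5, 7))
        self._xr = xr
        self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xr, y = self._xr, self._y
        mask = xr == y[:, :, :, None, :, None, :, None]
        counts = mask.sum(axis=(3, 5, 7), keepdims=True)
        dxr = mask * (dy[:, :, :, None, :, None, :, None] / counts)
        B, C = dy.shape[:2]
        X, Y, Z = dy.shape[2] * 2, dy.shape[3] * 2, dy.shape[4] * 2
        self._xr = self._y = None
        return dxr.reshape(B, C, X, Y, Z).astype(dy.dtype)


class Upsample2(Layer):
    """Nearest-neighbor 2x upsampling along each spatial axis."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, X, Y, Z = dy.shape
        return dy.reshape(B, C, X // 2, 2, Y // 2, 2, Z // 2, 2).sum(axis=(3, 5, 7))


class ConvBlock(Layer):
    """(Conv -> [BN] -> ReLU) x 2, the standard U-Net level block."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 batch_norm: bool = True, dtype=np.float32) -> None:
        super().__init__()
        self.layers: list[Layer] = []
        cin = in_channels
        for _ in range(2):
            self.layers.append(Conv3d(cin, out_channels, 3, rng=rng, dtype=dtype))
            if batch_norm:
                self.layers.append(BatchNorm3d(out_channels, dtype=dtype))
            self.layers.append(ReLU())
            cin = out_channels

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def named_params(self, prefix: str = ""):
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield f"{prefix}{i}.{name}", layer, name


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, named_params, momentum: float = 0.9) -> None:
        # named_params: iterable of (name, layer, param_key)
        self.entries = list(named_params)
        self.momentum = momentum
        self.velocity = {name: np.zeros_like(layer.params[key])
                         for name, layer, key in self.entries}

    def step(self, lr: float) -> None:
        for name, layer, key in self.entries:
            v = self.velocity[name]
            v *= self.momentum
            v -= lr * layer.grads[key]
            layer.params[key] += v
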