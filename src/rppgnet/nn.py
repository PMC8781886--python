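"""Minimal NumPy neural-network engine for the rPPG model.

Implements exactly the layer set the architecture needs — 3D convolution,
temporal central-difference convolution, ReLU, spatial average pooling,
adaptive spatial pooling, and the 3D attention block — each with a
hand-derived backward pass, plus a ``Sequential`` container and an Adam
optimizer.  Gradients are validated against numerical differentiation in
the test suite.

All activations are ``(N, C, T, H, W)``; parameters default to float32.
"""

from __future__ import annotations

import copy

import numpy as np

from .attention import CbamParams, sigmoid
from .cdc import (
    ConfigError,
    ShapeError,
    cdc_effective_kernel,
    cdc_kernel_grad,
    conv3d_backward,
    conv3d_forward,
)

__all__ = [
    "Param",
    "Layer",
    "Conv3d",
    "CdcConv3d",
    "ReLU",
    "AvgPool3d",
    "AdaptiveAvgPoolSpatial",
    "Cbam3dLayer",
    "SqueezeTrace",
    "Sequential",
    "Adam",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> dict[str, Param]:
        return {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _he_conv(rng: np.random.Generator, cout: int, cin: int, kernel, dtype) -> np.ndarray:
    fan_in = cin * int(np.prod(kernel))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, *kernel)).astype(dtype)


class Conv3d(Layer):
    """Plain 3D convolution (cross-correlation), stride/padding per axis."""

    def __init__(self, cin, cout, kernel, stride=(1, 1, 1), padding=(0, 0, 0),
                 bias=True, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.kernel, self.stride, self.padding = tuple(kernel), tuple(stride), tuple(padding)
        self.w = Param(_he_conv(rng, cout, cin, kernel, dtype))
        self.b = Param(np.zeros(cout, dtype=dtype)) if bias else None
        self._x = None

    def params(self):
        p = {"w": self.w}
        if self.b is not None:
            p["b"] = self.b
        return p

    def effective_kernel(self) -> np.ndarray:
        return self.w.value

    def forward(self, x):
        self._x = x
        b = self.b.value if self.b is not None else None
        return conv3d_forward(x, self.effective_kernel(), b, self.stride, self.padding)

    def backward(self, dy):
        dx, dw_eff, db = conv3d_backward(dy, self._x, self.effective_kernel(),
                                         self.stride, self.padding)
        self._accumulate_kernel_grad(dw_eff)
        if self.b is not None:
            self.b.grad += db
        self._x = None
        return dx

    def _accumulate_kernel_grad(self, dw_eff):
        self.w.grad += dw_eff


class CdcConv3d(Conv3d):
    """Temporal central-difference convolution layer.

    Folds the difference correction into an effective kernel at forward
    time; the backward pass maps the effective-kernel gradient back onto
    the raw weights (every adjacent-time tap also feeds the kernel center
    with weight ``-theta``).
    """

    def __init__(self, cin, cout, kernel=(3, 3, 3), theta=0.6, stride=(1, 1, 1),
                 padding=(0, 0, 0), bias=True, rng=None, dtype=np.float32):
        if any(k % 2 == 0 for k in kernel):
            raise ConfigError(f"kernel dims must be odd, got {kernel}")
        if not 0.0 <= theta <= 1.0:
            raise ConfigError(f"theta must be in [0, 1], got {theta}")
        super().__init__(cin, cout, kernel, stride, padding, bias, rng, dtype)
        self.theta = float(theta)

    def effective_kernel(self):
        return cdc_effective_kernel(self.w.value, self.theta)

    def _accumulate_kernel_grad(self, dw_eff):
        self.w.grad += cdc_kernel_grad(dw_eff, self.theta)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class AvgPool3d(Layer):
    """Average pooling with window = stride; the network only uses (1, 2, 2)."""

    def __init__(self, window=(1, 2, 2)):
        self.window = tuple(window)

    def forward(self, x):
        N, C, T, H, W = x.shape
        wt, wh, ww = self.window
        if T % wt or H % wh or W % ww:
            raise ShapeError(f"input {x.shape[2:]} not divisible by pool window {self.window}")
        self._in_shape = x.shape
        xr = x.reshape(N, C, T // wt, wt, H // wh, wh, W // ww, ww)
        return xr.mean(axis=(3, 5, 7))

    def backward(self, dy):
        wt, wh, ww = self.window
        scale = 1.0 / (wt * wh * ww)
        dx = np.broadcast_to(
            (dy * scale)[:, :, :, None, :, None, :, None],
            dy.shape[:2] + (dy.shape[2], wt, dy.shape[3], wh, dy.shape[4], ww),
        )
        return dx.reshape(self._in_shape)


class AdaptiveAvgPoolSpatial(Layer):
    """Pool H and W down to 1x1, preserving the temporal axis."""

    def forward(self, x):
        self._hw = x.shape[3:]
        return x.mean(axis=(3, 4), keepdims=True)

    def backward(self, dy):
        H, W = self._hw
        return np.broadcast_to(dy / (H * W), dy.shape[:3] + (H, W)).copy()


class Cbam3dLayer(Layer):
    """Channel attention then spatial attention, batched, with backward.

    Same math as the functional :mod:`rppgnet.attention` ops; the shared
    perceptron and the spatial convolution carry no biases.
    """

    def __init__(self, channels, reduction_ratio=16, spatial_kernel=7, rng=None, dtype=np.float32):
        self.p = CbamParams(channels, reduction_ratio, spatial_kernel)
        rng = rng or np.random.default_rng()
        c, r, k = channels, reduction_ratio, spatial_kernel
        self.w0 = Param(rng.normal(0.0, np.sqrt(2.0 / c), size=(c // r, c)).astype(dtype))
        self.w1 = Param(rng.normal(0.0, np.sqrt(2.0 / (c // r)), size=(c, c // r)).astype(dtype))
        self.ws = Param(rng.normal(0.0, np.sqrt(2.0 / (2 * k**3)), size=(1, 2, k, k, k)).astype(dtype))

    def params(self):
        return {"w0": self.w0, "w1": self.w1, "ws": self.ws}

    # -- channel stage -------------------------------------------------
    def _mlp(self, p):
        h = np.maximum(p @ self.w0.value.T, 0.0)
        return h, h @ self.w1.value.T

    def forward(self, x):
        N, C, T, H, W = x.shape
        xf = x.reshape(N, C, -1)
        p_avg = xf.mean(axis=2)
        self._imax_t = xf.argmax(axis=2)
        p_max = np.take_along_axis(xf, self._imax_t[:, :, None], axis=2)[:, :, 0]
        h_a, z_a = self._mlp(p_avg)
        h_m, z_m = self._mlp(p_max)
        m = sigmoid(z_a + z_m)
        x_prime = x * m[:, :, None, None, None]

        avg_c = x_prime.mean(axis=1, keepdims=True)
        self._imax_c = x_prime.argmax(axis=1)
        max_c = np.take_along_axis(x_prime, self._imax_c[:, None], axis=1)
        stacked = np.concatenate([avg_c, max_c], axis=1)
        pad = self.p.spatial_kernel // 2
        logits = conv3d_forward(stacked, self.ws.value, None, padding=(pad,) * 3)
        s = sigmoid(logits)

        self._cache = (x, p_avg, p_max, h_a, h_m, m, x_prime, stacked, s)
        return x_prime * s

    def backward(self, dy):
        x, p_avg, p_max, h_a, h_m, m, x_prime, stacked, s = self._cache
        self._cache = None
        N, C, T, H, W = x.shape
        pad = self.p.spatial_kernel // 2

        # spatial stage
        dxp = dy * s
        ds = (dy * x_prime).sum(axis=1, keepdims=True)
        dlogits = ds * s * (1.0 - s)
        dstacked, dws, _ = conv3d_backward(dlogits, stacked, self.ws.value, padding=(pad,) * 3)
        self.ws.grad += dws
        dxp += dstacked[:, 0:1] / C  # channel-average path
        dmax_c = np.zeros_like(x_prime)
        np.put_along_axis(dmax_c, self._imax_c[:, None], dstacked[:, 1:2], axis=1)
        dxp += dmax_c

        # channel stage
        dx = dxp * m[:, :, None, None, None]
        dm = (dxp * x).sum(axis=(2, 3, 4))
        dz = dm * m * (1.0 - m)
        dp = []
        for h, p in ((h_a, p_avg), (h_m, p_max)):
            self.w1.grad += dz.T @ h
            dh = (dz @ self.w1.value) * (h > 0)
            self.w0.grad += dh.T @ p
            dp.append(dh @ self.w0.value)
        dx += (dp[0] / (T * H * W))[:, :, None, None, None]
        dmax_t = np.zeros((N, C, T * H * W), dtype=dx.dtype)
        np.put_along_axis(dmax_t, self._imax_t[:, :, None], dp[1][:, :, None], axis=2)
        dx += dmax_t.reshape(x.shape)
        self._imax_t = self._imax_c = None
        return dx


class SqueezeTrace(Layer):
    """(N, 1, T, 1, 1) -> (N, T) at the network head."""

    def forward(self, x):
        self._shape = x.shape
        return x[:, 0, :, 0, 0]

    def backward(self, dy):
        dx = np.zeros(self._shape, dtype=dy.dtype)
        dx[:, 0, :, 0, 0] = dy
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params().items():
                out[f"{i}.{type(layer).__name__}.{name}"] = p
        return out

    def zero_grad(self):
        for p in self.params().values():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.value.copy() for k, p in self.params().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, p in params.items():
            if p.value.shape != state[k].shape:
                raise ShapeError(f"{k}: shape {state[k].shape} != {p.value.shape}")
            p.value[...] = state[k]

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})

    def copy_state(self) -> dict[str, np.ndarray]:
        return copy.deepcopy(self.state_dict())


class Adam:
    def __init__(self, params: dict[str, Param], lr=2e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p.value -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
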