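"""Temporal central-difference convolution (3DCDC-T).

A conventional 3D convolution aggregates intensities over a local
spatiotemporal receptive field.  The temporal central-difference variant
adds a gradient-level term: for every output position the center input
intensity, weighted by the sum of the kernel taps that look at *other*
time steps, is subtracted.  A hyperparameter ``theta`` in [0, 1] blends
the two contributions (``theta = 0`` recovers plain convolution).

Because the correction is linear in the kernel, the whole operator can be
folded into a single convolution with an *effective kernel*: the original
weights plus ``-theta * sum(adjacent-time taps)`` placed at the kernel
center.  :func:`cdc3dt_forward` uses that folded form; the nested-loop
:func:`cdc3dt_reference` evaluates the definition directly and serves as
the correctness oracle.

Array convention throughout: channels-first, ``(C, T, H, W)`` for a single
sample and ``(N, C, T, H, W)`` batched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.fft as _sfft

__all__ = [
    "CdcSpec",
    "ReceptiveFieldSplit",
    "split_receptive_field",
    "cdc3dt_reference",
    "cdc3dt_forward",
    "cdc_effective_kernel",
    "conv3d_forward",
    "conv3d_backward",
]


class ShapeError(ValueError):
    """Input/weight shapes are inconsistent."""


class ConfigError(ValueError):
    """Invalid layer hyperparameters."""


@dataclass(frozen=True)
class CdcSpec:
    """Hyperparameters of one temporal central-difference convolution layer.

    Parameters
    ----------
    in_channels, out_channels
        Channel counts of input and output feature maps.
    kernel
        ``(kt, kh, kw)`` extents; each must be odd so the receptive field
        has a well-defined center.
    theta
        Contribution of the temporal-difference term, in ``[0, 1]``.
    stride, padding
        Per-axis stride and symmetric zero padding ``(t, h, w)``.
    bias
        Whether a per-output-channel bias is added after the combined sum.
    """

    in_channels: int
    out_channels: int
    kernel: tuple[int, int, int] = (3, 3, 3)
    theta: float = 0.6
    stride: tuple[int, int, int] = (1, 1, 1)
    padding: tuple[int, int, int] = (0, 0, 0)
    bias: bool = True

    def __post_init__(self) -> None:
        if any(k <= 0 or k % 2 == 0 for k in self.kernel):
            raise ConfigError(f"kernel dims must be odd and positive, got {self.kernel}")
        if not 0.0 <= self.theta <= 1.0:
            raise ConfigError(f"theta must be in [0, 1], got {self.theta}")
        if self.in_channels <= 0 or self.out_channels <= 0:
            raise ConfigError("channel counts must be positive")


@dataclass(frozen=True)
class ReceptiveFieldSplit:
    """Kernel offsets partitioned by temporal position.

    ``current_step`` holds offsets whose temporal index equals the kernel's
    temporal center; ``adjacent_steps`` holds all the rest.  Offsets are
    ``(dt, dh, dw)`` indices into the kernel (0-based).
    """

    current_step: tuple[tuple[int, int, int], ...]
    adjacent_steps: tuple[tuple[int, int, int], ...]


def split_receptive_field(kernel: Sequence[int]) -> ReceptiveFieldSplit:
    """Partition kernel taps into current-time-step and adjacent-time-step sets."""
    kt, kh, kw = kernel
    if any(k <= 0 or k % 2 == 0 for k in (kt, kh, kw)):
        raise ConfigError(f"kernel dims must be odd and positive, got {tuple(kernel)}")
    ct = kt // 2
    current, adjacent = [], []
    for dt in range(kt):
        for dh in range(kh):
            for dw in range(kw):
                (current if dt == ct else adjacent).append((dt, dh, dw))
    return ReceptiveFieldSplit(tuple(current), tuple(adjacent))


# ---------------------------------------------------------------------------
# plain 3D convolution (correlation, no kernel flip), channels-first
# ---------------------------------------------------------------------------


def _out_len(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


# Kernels with at least this many taps go through the FFT path (only
# unit stride); the 7x7x7 attention kernel qualifies, 3x3x3 does not.
_FFT_TAP_THRESHOLD = 100


def conv3d_forward(
    x: np.ndarray,
    w: np.ndarray,
    b: np.ndarray | None = None,
    stride: tuple[int, int, int] = (1, 1, 1),
    padding: tuple[int, int, int] = (0, 0, 0),
) -> np.ndarray:
    """Batched 3D cross-correlation.

    ``x``: (N, Cin, T, H, W); ``w``: (Cout, Cin, kt, kh, kw); returns
    (N, Cout, T', H', W').  Small kernels run as one matmul per kernel tap
    (memory stays linear in the input); large kernels at unit stride go
    through an FFT circular correlation.
    """
    if x.ndim != 5 or w.ndim != 5 or x.shape[1] != w.shape[1]:
        raise ShapeError(f"inconsistent shapes x={x.shape}, w={w.shape}")
    N, Ci, T, H, W = x.shape
    Co, _, kt, kh, kw = w.shape
    st, sh, sw = stride
    pt, ph, pw = padding
    To, Ho, Wo = _out_len(T, kt, st, pt), _out_len(H, kh, sh, ph), _out_len(W, kw, sw, pw)
    if min(To, Ho, Wo) <= 0:
        raise ShapeError(f"kernel {w.shape[2:]} larger than padded input {x.shape[2:]}")
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
    if kt * kh * kw >= _FFT_TAP_THRESHOLD and stride == (1, 1, 1):
        y = _fft_correlate(xp, w)[:, :, :To, :Ho, :Wo]
    else:
        dtype = np.result_type(x, w)
        y = np.zeros((N, Co, To * Ho * Wo), dtype=dtype)
        for dt in range(kt):
            for dh in range(kh):
                for dw in range(kw):
                    xs = np.ascontiguousarray(
                        xp[:, :, dt : dt + st * To : st, dh : dh + sh * Ho : sh, dw : dw + sw * Wo : sw]
                    ).reshape(N, Ci, -1)
                    y += np.matmul(w[:, :, dt, dh, dw].astype(dtype), xs)
        y = y.reshape(N, Co, To, Ho, Wo)
    if b is not None:
        y = y + b[None, :, None, None, None]
    return y


def conv3d_backward(
    dy: np.ndarray,
    x: np.ndarray,
    w: np.ndarray,
    stride: tuple[int, int, int] = (1, 1, 1),
    padding: tuple[int, int, int] = (0, 0, 0),
    need_dx: bool = True,
) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    """Gradients of :func:`conv3d_forward`; returns ``(dx, dw, db)``."""
    N, Ci, T, H, W = x.shape
    Co, _, kt, kh, kw = w.shape
    st, sh, sw = stride
    pt, ph, pw = padding
    To, Ho, Wo = dy.shape[2:]
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
    db = dy.sum(axis=(0, 2, 3, 4))
    if kt * kh * kw >= _FFT_TAP_THRESHOLD and stride == (1, 1, 1):
        dxp, dw = _fft_correlate_grads(dy, xp, w, need_dx)
    else:
        dxp = np.zeros_like(xp) if need_dx else None
        dw = np.zeros_like(w)
        dyf = dy.reshape(N, Co, -1)
        for dt in range(kt):
            for dh in range(kh):
                for dw_ in range(kw):
                    sl = (
                        slice(None),
                        slice(None),
                        slice(dt, dt + st * To, st),
                        slice(dh, dh + sh * Ho, sh),
                        slice(dw_, dw_ + sw * Wo, sw),
                    )
                    xs = np.ascontiguousarray(xp[sl]).reshape(N, Ci, -1)
                    dw[:, :, dt, dh, dw_] = np.matmul(dyf, xs.transpose(0, 2, 1)).sum(axis=0)
                    if need_dx:
                        dxp[sl] += np.matmul(w[:, :, dt, dh, dw_].T.astype(dy.dtype), dyf).reshape(
                            N, Ci, To, Ho, Wo
                        )
    dx = None
    if need_dx:
        dx = dxp[:, :, pt : pt + T, ph : ph + H, pw : pw + W]
    return dx, dw.astype(w.dtype, copy=False), db


def _fft_correlate(xp: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Circular cross-correlation of padded input with the kernel via FFT.

    Valid output positions are the leading (Tp-kt+1, ...) block.
    """
    shape = xp.shape[2:]
    Xf = _sfft.rfftn(xp, s=shape, axes=(2, 3, 4))
    Wf = _sfft.rfftn(w.astype(xp.dtype, copy=False), s=shape, axes=(2, 3, 4))
    Yf = np.einsum("ncthw,octhw->nothw", Xf, np.conj(Wf), optimize=True)
    return _sfft.irfftn(Yf, s=shape, axes=(2, 3, 4)).astype(xp.dtype, copy=False)


def _fft_correlate_grads(dy, xp, w, need_dx):
    N, Ci = xp.shape[:2]
    Co, _, kt, kh, kw = w.shape
    shape = xp.shape[2:]
    dyp = np.zeros((N, Co, *shape), dtype=dy.dtype)
    dyp[:, :, : dy.shape[2], : dy.shape[3], : dy.shape[4]] = dy
    DYf = _sfft.rfftn(dyp, s=shape, axes=(2, 3, 4))
    Xf = _sfft.rfftn(xp, s=shape, axes=(2, 3, 4))
    # dw[k] = sum_p dy[p] x[p+k]  -> correlation of x with dy
    DWf = np.einsum("ncthw,nothw->octhw", Xf, np.conj(DYf), optimize=True)
    dw_full = _sfft.irfftn(DWf, s=shape, axes=(2, 3, 4))
    dw = dw_full[:, :, :kt, :kh, :kw]
    dxp = None
    if need_dx:
        # dx[q] = sum_p dy[p] w[q-p]  -> convolution of dy with the kernel
        Wf = _sfft.rfftn(w.astype(dyp.dtype, copy=False), s=shape, axes=(2, 3, 4))
        DXf = np.einsum("nothw,octhw->ncthw", DYf, Wf, optimize=True)
        dxp = _sfft.irfftn(DXf, s=shape, axes=(2, 3, 4)).astype(xp.dtype, copy=False)
    return dxp, dw


# ---------------------------------------------------------------------------
# temporal central-difference convolution
# ---------------------------------------------------------------------------


def cdc_effective_kernel(w: np.ndarray, theta: float) -> np.ndarray:
    """Fold the temporal-difference correction into the kernel.

    The correction subtracts ``theta * x(center) * sum(adjacent-time taps)``,
    i.e. adds ``-theta * S`` at the kernel center where ``S`` sums the taps
    with nonzero temporal offset.
    """
    Co, Ci, kt, kh, kw = w.shape
    adj_sum = w.sum(axis=(2, 3, 4)) - w[:, :, kt // 2].sum(axis=(2, 3))
    w_eff = w.copy()
    w_eff[:, :, kt // 2, kh // 2, kw // 2] -= theta * adj_sum
    return w_eff


def cdc_kernel_grad(dw_eff: np.ndarray, theta: float) -> np.ndarray:
    """Map a gradient w.r.t. the effective kernel back to the raw kernel."""
    Co, Ci, kt, kh, kw = dw_eff.shape
    dw = dw_eff.copy()
    g_center = dw_eff[:, :, kt // 2, kh // 2, kw // 2]
    # every adjacent-time tap also feeds the center through -theta * S
    mask = np.ones((kt, kh, kw), dtype=dw.dtype)
    mask[kt // 2] = 0.0
    dw -= theta * g_center[:, :, None, None, None] * mask
    return dw


def cdc3dt_forward(
    x: np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray | None,
    spec: CdcSpec,
) -> np.ndarray:
    """Temporal central-difference convolution via the folded effective kernel."""
    _check_cdc_shapes(x, weights, spec)
    w_eff = cdc_effective_kernel(weights, spec.theta)
    b = bias if spec.bias else None
    squeeze = x.ndim == 4
    xb = x[None] if squeeze else x
    y = conv3d_forward(xb, w_eff, b, spec.stride, spec.padding)
    return y[0] if squeeze else y


def cdc3dt_reference(
    x: np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray | None,
    spec: CdcSpec,
) -> np.ndarray:
    """Nested-loop evaluation of the defining sum (the oracle).

    At each output position: the vanilla windowed weighted sum, plus
    ``theta * (-x(center) * sum of adjacent-time taps)``.  Intended only
    for small arrays.
    """
    _check_cdc_shapes(x, weights, spec)
    squeeze = x.ndim == 4
    xb = x[None] if squeeze else x
    N, Ci, T, H, W = xb.shape
    Co, _, kt, kh, kw = weights.shape
    st, sh, sw = spec.stride
    pt, ph, pw = spec.padding
    To, Ho, Wo = _out_len(T, kt, st, pt), _out_len(H, kh, sh, ph), _out_len(W, kw, sw, pw)
    split = split_receptive_field((kt, kh, kw))
    xp = np.pad(xb.astype(np.float64), ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
    y = np.zeros((N, Co, To, Ho, Wo))
    for n in range(N):
        for o in range(Co):
            for t in range(To):
                for i in range(Ho):
                    for j in range(Wo):
                        acc = 0.0
                        for c in range(Ci):
                            for dt, dh, dw in split.current_step + split.adjacent_steps:
                                acc += weights[o, c, dt, dh, dw] * xp[n, c, t * st + dt, i * sh + dh, j * sw + dw]
                            adj = sum(weights[o, c, dt, dh, dw] for dt, dh, dw in split.adjacent_steps)
                            center = xp[n, c, t * st + kt // 2, i * sh + kh // 2, j * sw + kw // 2]
                            acc += spec.theta * (-center * adj)
                        if spec.bias and bias is not None:
                            acc += bias[o]
                        y[n, o, t, i, j] = acc
    return y[0] if squeeze else y


def _check_cdc_shapes(x: np.ndarray, weights: np.ndarray, spec: CdcSpec) -> None:
    cin = x.shape[0] if x.ndim == 4 else x.shape[1]
    if x.ndim not in (4, 5):
        raise ShapeError(f"expected 4D or 5D input, got {x.shape}")
    if weights.shape != (spec.out_channels, spec.in_channels, *spec.kernel):
        raise ShapeError(f"weights {weights.shape} do not match spec {spec}")
    if cin != spec.in_channels:
        raise ShapeError(f"input has {cin} channels, spec expects {spec.in_channels}")
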