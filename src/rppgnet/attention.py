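"""3D convolutional block attention (channel attention then spatial attention).

Channel attention squeezes the feature map with global average- and
max-pooling over (T, H, W), pushes both descriptors through one shared
two-layer perceptron (C -> C/r -> C, ReLU inside, no biases), sums the two
outputs and applies a sigmoid; the resulting per-channel weights rescale
the input.  Spatial attention then pools the refined map across channels
(average and maximum), convolves the 2-channel stack with a single odd
kernel (default 7x7x7, "same" padding) and applies a sigmoid to obtain a
per-voxel weight map.

These are the *functional* definitions used both by the network layers in
:mod:`rppgnet.nn` and by tests; weights are passed in explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cdc import ConfigError, ShapeError, conv3d_forward

__all__ = [
    "CbamParams",
    "CbamWeights",
    "init_cbam_weights",
    "channel_attention",
    "spatial_attention",
    "cbam3d",
    "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.result_type(z, np.float32))
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class CbamParams:
    """Shape hyperparameters of one attention block."""

    channels: int
    reduction_ratio: int = 16
    spatial_kernel: int = 7

    def __post_init__(self) -> None:
        if self.channels % self.reduction_ratio != 0:
            raise ConfigError(
                f"channels ({self.channels}) must be divisible by "
                f"reduction_ratio ({self.reduction_ratio})"
            )
        if self.spatial_kernel % 2 == 0 or self.spatial_kernel <= 0:
            raise ConfigError(f"spatial_kernel must be odd, got {self.spatial_kernel}")


@dataclass
class CbamWeights:
    """w0: (C/r, C) squeeze; w1: (C, C/r) expand; w_spatial: (1, 2, k, k, k)."""

    w0: np.ndarray
    w1: np.ndarray
    w_spatial: np.ndarray


def init_cbam_weights(params: CbamParams, rng: np.random.Generator, dtype=np.float64) -> CbamWeights:
    c, r, k = params.channels, params.reduction_ratio, params.spatial_kernel
    w0 = rng.normal(0.0, np.sqrt(2.0 / c), size=(c // r, c)).astype(dtype)
    w1 = rng.normal(0.0, np.sqrt(2.0 / (c // r)), size=(c, c // r)).astype(dtype)
    ws = rng.normal(0.0, np.sqrt(2.0 / (2 * k**3)), size=(1, 2, k, k, k)).astype(dtype)
    return CbamWeights(w0, w1, ws)


def _shared_mlp(p: np.ndarray, w: CbamWeights) -> np.ndarray:
    # p: (C,) descriptor -> (C,) logits through the shared biasless perceptron
    return np.maximum(p @ w.w0.T, 0.0) @ w.w1.T


def channel_attention(F: np.ndarray, params: CbamParams, weights: CbamWeights) -> np.ndarray:
    """Per-channel attention map, shape (C, 1, 1, 1), values in (0, 1)."""
    if F.ndim != 4 or F.shape[0] != params.channels:
        raise ShapeError(f"expected (C={params.channels}, T, H, W), got {F.shape}")
    p_avg = F.mean(axis=(1, 2, 3))
    p_max = F.max(axis=(1, 2, 3))
    logits = _shared_mlp(p_avg, weights) + _shared_mlp(p_max, weights)
    return sigmoid(logits)[:, None, None, None]


def spatial_attention(F_prime: np.ndarray, params: CbamParams, weights: CbamWeights) -> np.ndarray:
    """Per-voxel attention map, shape (1, T, H, W), values in (0, 1)."""
    if F_prime.ndim != 4:
        raise ShapeError(f"expected (C, T, H, W), got {F_prime.shape}")
    avg_c = F_prime.mean(axis=0, keepdims=True)
    max_c = F_prime.max(axis=0, keepdims=True)
    stacked = np.concatenate([avg_c, max_c], axis=0)[None]  # (1, 2, T, H, W)
    pad = params.spatial_kernel // 2
    logits = conv3d_forward(stacked, weights.w_spatial, None, padding=(pad, pad, pad))[0]
    return sigmoid(logits)


def cbam3d(F: np.ndarray, params: CbamParams, weights: CbamWeights) -> np.ndarray:
    """Channel attention followed by spatial attention; output shape equals input."""
    F_prime = F * channel_attention(F, params, weights)
    F_dprime = F_prime * spatial_attention(F_prime, params, weights)
    return F_dprime
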