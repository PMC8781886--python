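"""Assembly of the rPPG network.

The architecture maps a clip of stitched skin ROIs, shape
``(T, 96, 96, 3)``, to a length-``T`` pulse trace:

    stem conv (1x5x5, 3->16) -> AvgPool (1x2x2)
    -> [CDC+attention block -> AvgPool (1x2x2)] x 3
    -> CDC+attention block
    -> adaptive average pool to 1x1 spatial -> 1x1x1 conv (64->1)

Every block is two temporal central-difference convolutions (the first
changes the channel count, the second preserves it) followed by the 3D
attention module; ReLU follows every convolution except the final 1x1x1
head, which stays linear so the trace can be zero-centered.  All pooling
is spatial only, so the temporal resolution of the output equals the
input clip length.  The default configuration has ~0.66 M parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cdc import ConfigError, ShapeError
from .nn import (
    AdaptiveAvgPoolSpatial,
    AvgPool3d,
    Cbam3dLayer,
    CdcConv3d,
    Conv3d,
    ReLU,
    Sequential,
    SqueezeTrace,
)

__all__ = [
    "NetworkConfig",
    "RppgPrediction",
    "build_network",
    "count_parameters",
    "predict_clip",
    "shape_chain",
]

MAX_INTENSITY = 255.0


@dataclass(frozen=True)
class NetworkConfig:
    clip_len: int = 128
    in_size: tuple[int, int] = (96, 96)
    in_channels: int = 3
    stem_channels: int = 16
    stem_kernel: tuple[int, int, int] = (1, 5, 5)
    block_channels: tuple[int, ...] = (32, 64, 64, 64)
    block_kernel: tuple[int, int, int] = (3, 3, 3)
    theta: float = 0.6
    cbam_reduction: int = 16
    spatial_kernel: int = 7

    def __post_init__(self) -> None:
        for k in (self.stem_kernel, self.block_kernel, (self.spatial_kernel,)):
            if any(d % 2 == 0 or d <= 0 for d in k):
                raise ConfigError(f"kernel dims must be odd and positive, got {k}")
        if not self.block_channels:
            raise ConfigError("at least one block required")
        # each block halves H and W except the last; the chain must stay integral
        h, w = self.in_size
        for _ in range(len(self.block_channels)):
            if h % 2 or w % 2:
                raise ConfigError(f"in_size {self.in_size} not divisible through the pooling chain")
            h, w = h // 2, w // 2


@dataclass
class RppgPrediction:
    """Raw network output for one clip (before any filtering)."""

    signal: np.ndarray
    start_frame: int = 0
    frame_rate: float = 30.0


def build_network(config: NetworkConfig, rng: np.random.Generator | None = None) -> Sequential:
    """Construct the model; weights drawn He-normal from ``rng``."""
    rng = rng or np.random.default_rng()
    sk = config.stem_kernel
    stem_pad = (sk[0] // 2, sk[1] // 2, sk[2] // 2)
    layers: list = [
        Conv3d(config.in_channels, config.stem_channels, sk, padding=stem_pad, rng=rng),
        ReLU(),
        AvgPool3d((1, 2, 2)),
    ]
    cin = config.stem_channels
    bk = config.block_kernel
    bpad = (bk[0] // 2, bk[1] // 2, bk[2] // 2)
    n_blocks = len(config.block_channels)
    for i, cout in enumerate(config.block_channels):
        layers += [
            CdcConv3d(cin, cout, bk, theta=config.theta, padding=bpad, rng=rng),
            ReLU(),
            CdcConv3d(cout, cout, bk, theta=config.theta, padding=bpad, rng=rng),
            ReLU(),
            Cbam3dLayer(cout, config.cbam_reduction, config.spatial_kernel, rng=rng),
        ]
        if i < n_blocks - 1:
            layers.append(AvgPool3d((1, 2, 2)))
        cin = cout
    layers += [
        AdaptiveAvgPoolSpatial(),
        Conv3d(cin, 1, (1, 1, 1), rng=rng),
        SqueezeTrace(),
    ]
    return Sequential(layers)


def count_parameters(model: Sequential) -> int:
    """Number of independently trainable scalars."""
    return int(sum(p.value.size for p in model.params().values()))


def shape_chain(config: NetworkConfig) -> list[tuple[str, tuple[int, int, int, int]]]:
    """Analytic (T, H, W, C) after each named stage, mirroring the layer table."""
    T = config.clip_len
    h, w = config.in_size
    rows = [("input", (T, h, w, config.in_channels))]
    rows.append(("stem_conv", (T, h, w, config.stem_channels)))
    h, w = h // 2, w // 2
    rows.append(("avg_pool_0", (T, h, w, config.stem_channels)))
    n_blocks = len(config.block_channels)
    for i, c in enumerate(config.block_channels):
        rows.append((f"block_{i + 1}", (T, h, w, c)))
        if i < n_blocks - 1:
            h, w = h // 2, w // 2
            rows.append((f"avg_pool_{i + 1}", (T, h, w, c)))
    rows.append(("adaptive_pool", (T, 1, 1, config.block_channels[-1])))
    rows.append(("head_conv", (T, 1, 1, 1)))
    return rows


def predict_clip(model: Sequential, clip: np.ndarray, start_frame: int = 0,
                 frame_rate: float = 30.0) -> RppgPrediction:
    """Forward one ROI clip, shape (T, H, W, 3), intensity 0..255.

    Frames are scaled to [0, 1] and moved to channels-first before the
    forward pass; the output is the raw length-T rPPG trace.
    """
    if clip.ndim != 4 or clip.shape[-1] != 3:
        raise ShapeError(f"expected (T, H, W, 3) clip, got {clip.shape}")
    x = np.ascontiguousarray(clip.transpose(3, 0, 1, 2), dtype=np.float32) / MAX_INTENSITY
    trace = model.forward(x[None])[0]
    return RppgPrediction(signal=np.asarray(trace, dtype=np.float64),
                          start_frame=start_frame, frame_rate=frame_rate)
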