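"""Negative-Pearson loss and the optimization loop.

The network is trained to reproduce the *shape* of the reference pulse,
not its scale or offset (contact PPG and video-derived rPPG share trend
only), so the loss is ``1 - r`` with ``r`` the Pearson correlation between
predicted and reference traces; it lies in [0, 2] and is invariant under
positive affine rescaling of either signal.  Optimization follows the
standard recipe: Adam, learning rate 2e-4, batch size 8, 30 epochs,
left-right flip augmentation; everything is seeded and the best state by
validation loss is retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import MAX_INTENSITY
from .nn import Adam, Sequential
from .roi import RoiClip

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "AlignedPair",
    "neg_pearson_loss",
    "neg_pearson_batch",
    "flip_augment",
    "train",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 2e-4
    batch_size: int = 8
    epochs: int = 30
    clip_len: int = 128
    clip_stride: int = 8
    flip_augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs,
               self.clip_len, self.clip_stride) <= 0:
            raise ValueError(f"all numeric training fields must be positive: {self}")


@dataclass(frozen=True)
class AlignedPair:
    """Equal-length predicted and reference traces for one clip."""

    predicted: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.predicted, dtype=np.float64)
        y = np.asarray(self.reference, dtype=np.float64)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError(f"traces must be equal-length 1-D, got {x.shape} vs {y.shape}")
        object.__setattr__(self, "predicted", x)
        object.__setattr__(self, "reference", y)


def neg_pearson_loss(pair: AlignedPair) -> float:
    """``1 - pearson_r(predicted, reference)``; 1.0 if either trace is constant."""
    loss, _ = _neg_pearson(pair.predicted[None], pair.reference[None])
    return float(loss)


def neg_pearson_batch(pred: np.ndarray, ref: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean loss over a (N, T) batch and its gradient w.r.t. ``pred``."""
    return _neg_pearson(pred, ref)


def _neg_pearson(pred: np.ndarray, ref: np.ndarray) -> tuple[float, np.ndarray]:
    x = pred - pred.mean(axis=1, keepdims=True)
    y = ref - ref.mean(axis=1, keepdims=True)
    sx = np.sqrt((x**2).sum(axis=1))
    sy = np.sqrt((y**2).sum(axis=1))
    grad = np.zeros_like(pred, dtype=np.float64)
    ok = (sx > 0) & (sy > 0)
    if not ok.all():
        warnings.warn("zero-variance trace in loss; contributing loss 1 with no gradient")
    r = np.zeros(len(x))
    if ok.any():
        r[ok] = (x[ok] * y[ok]).sum(axis=1) / (sx[ok] * sy[ok])
        # d(1-r)/dx_i = -(y_i/(sx*sy) - r*x_i/sx^2); centering terms vanish
        grad[ok] = -(
            y[ok] / (sx[ok] * sy[ok])[:, None] - r[ok][:, None] * x[ok] / (sx[ok] ** 2)[:, None]
        ) / len(x)
    loss = float(np.mean(1.0 - np.where(ok, r, 0.0)))
    return loss, grad


def flip_augment(clip: RoiClip) -> RoiClip:
    """Mirror every frame left-right; the pulse label is unchanged."""
    return RoiClip(frames=clip.frames[:, :, ::-1].copy(),
                   start_frame=clip.start_frame, frame_rate=clip.frame_rate)


def _to_batch(clips: list[np.ndarray]) -> np.ndarray:
    # (B, T, H, W, 3) uint8 -> (B, 3, T, H, W) float32 in [0, 1]
    arr = np.stack(clips).astype(np.float32) / MAX_INTENSITY
    return np.ascontiguousarray(arr.transpose(0, 4, 1, 2, 3))


def train(
    model: Sequential,
    clips: list[np.ndarray],
    labels: list[np.ndarray],
    config: TrainConfig,
    val_clips: list[np.ndarray] | None = None,
    val_labels: list[np.ndarray] | None = None,
) -> dict:
    """Fit ``model``; returns ``{"train_loss": [...], "val_loss": [...]}`` per epoch.

    ``clips`` are (T, H, W, 3) intensity arrays, ``labels`` the frame-aligned
    reference traces.  When a validation set is given, the parameter state
    with the lowest validation loss is restored at the end.
    """
    if not clips:
        raise ValueError("empty training set")
    if len(clips) != len(labels):
        raise ValueError(f"{len(clips)} clips but {len(labels)} labels")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate)
    labels_arr = np.stack([np.asarray(l, dtype=np.float64) for l in labels])
    n = len(clips)
    history: dict = {"train_loss": [], "val_loss": []}
    best_val, best_state = np.inf, None
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i0 in range(0, n, config.batch_size):
            idx = order[i0 : i0 + config.batch_size]
            xb = _to_batch([clips[i] for i in idx])
            yb = labels_arr[idx]
            pred = model.forward(xb)
            loss, dpred = neg_pearson_batch(pred, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {i0 // config.batch_size}: {loss}"
                )
            model.zero_grad()
            model.backward(dpred.astype(np.float32))
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if val_clips:
            vloss = evaluate_loss(model, val_clips, val_labels, config.batch_size)
            history["val_loss"].append(vloss)
            if vloss < best_val:
                best_val, best_state = vloss, model.copy_state()
            logger.info("epoch %d: train_loss=%.4f val_loss=%.4f",
                        epoch, history["train_loss"][-1], vloss)
        else:
            logger.info("epoch %d: train_loss=%.4f", epoch, history["train_loss"][-1])
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


def evaluate_loss(model: Sequential, clips, labels, batch_size: int = 8) -> float:
    """Mean negative-Pearson loss over a clip set (no parameter updates)."""
    losses, weights = [], []
    for i0 in range(0, len(clips), batch_size):
        xb = _to_batch(clips[i0 : i0 + batch_size])
        yb = np.stack([np.asarray(l, dtype=np.float64) for l in labels[i0 : i0 + batch_size]])
        pred = model.forward(xb)
        loss, _ = neg_pearson_batch(pred, yb)
        losses.append(loss)
        weights.append(len(xb))
    return float(np.average(losses, weights=weights))
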