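"""ROI geometry: landmarks -> cheek/forehead boxes -> stitched clips.

The pulse signal lives in facial skin; the cheek band and the forehead are
the two largest skin regions, so they are cropped from each frame using a
standard 68-point landmark set (0-based indexing: jaw 0-16, brows 17-26,
eyes 36-47, mouth 48-67) and stitched into one square image: the cheek
crop resized to the top two thirds, the forehead crop to the bottom third
(96x96 by default: 64x96 over 32x96).

Box construction, image coordinates y-down, origin top-left:

* cheek — left edge at jaw point 3, top at the lowest of the four
  lower-eyelid points (40, 41, 46, 47), right edge at jaw point 13,
  bottom at the higher of the two upper-lip points (50, 52);
* forehead — spans brow mid-points 19 to 24 horizontally, extends upward
  from the higher brow by half the cheek height.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize as _resize

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkSet",
    "RoiBox",
    "RoiClip",
    "DegenerateRoiError",
    "LandmarkFormatError",
    "parse_landmarks",
    "write_landmarks",
    "cheek_box",
    "forehead_box",
    "crop_resize_stitch",
    "build_clips",
]

N_LANDMARKS = 68
# landmark indices used by the box geometry (0-based convention)
JAW_LEFT, JAW_RIGHT = 3, 13
BROW_LEFT, BROW_RIGHT = 19, 24
LOWER_EYELIDS = (40, 41, 46, 47)
UPPER_LIP = (50, 52)


class DegenerateRoiError(ValueError):
    """Face geometry yields a box with non-positive area or no frame overlap."""


class LandmarkFormatError(ValueError):
    """Landmark file violates the expected dialect."""


@dataclass(frozen=True)
class LandmarkSet:
    """68 (x, y) pixel coordinates for one frame."""

    points: np.ndarray  # (68, 2) float
    frame_index: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.shape != (N_LANDMARKS, 2):
            raise LandmarkFormatError(f"expected (68, 2) points, got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise LandmarkFormatError(f"non-finite landmark in frame {self.frame_index}")
        object.__setattr__(self, "points", pts)

    def x(self, i: int) -> float:
        return float(self.points[i, 0])

    def y(self, i: int) -> float:
        return float(self.points[i, 1])


@dataclass(frozen=True)
class RoiBox:
    x_left: float
    y_top: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise DegenerateRoiError(f"non-positive box dimensions: {self}")


@dataclass
class RoiClip:
    """Contiguous stack of stitched frames, (T, H, W, 3)."""

    frames: np.ndarray
    start_frame: int
    frame_rate: float = 30.0

    def __len__(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# landmark file dialect: header `frame,x_0..x_67,y_0..y_67`, one row per frame
# ---------------------------------------------------------------------------

_COLUMNS = ["frame"] + [f"x_{i}" for i in range(N_LANDMARKS)] + [f"y_{i}" for i in range(N_LANDMARKS)]


def parse_landmarks(path: str | Path) -> list[LandmarkSet]:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas raises several parser error types
        raise LandmarkFormatError(f"{path}: cannot parse landmark CSV: {exc}") from exc
    if list(df.columns) != _COLUMNS:
        raise LandmarkFormatError(
            f"{path}: expected columns frame,x_0..x_67,y_0..y_67 "
            f"({len(_COLUMNS)} columns), got {len(df.columns)}"
        )
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            vals = np.asarray(row[1:], dtype=np.float64)
        except (TypeError, ValueError) as exc:
            raise LandmarkFormatError(f"{path}: malformed row {i} ({exc})") from exc
        if not np.all(np.isfinite(vals)):
            raise LandmarkFormatError(f"{path}: malformed row {i} (non-numeric or missing values)")
        pts = np.column_stack([vals[:N_LANDMARKS], vals[N_LANDMARKS:]])
        out.append(LandmarkSet(points=pts, frame_index=int(row[0])))
    return out


def write_landmarks(landmarks: Iterable[LandmarkSet], path: str | Path) -> None:
    rows = []
    for lms in landmarks:
        rows.append([lms.frame_index, *lms.points[:, 0], *lms.points[:, 1]])
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# box geometry
# ---------------------------------------------------------------------------


def cheek_box(lms: LandmarkSet) -> RoiBox:
    """Cheek band between the jaw sides, lower eyelids and upper lip."""
    x_left = lms.x(JAW_LEFT)
    y_top = max(lms.y(i) for i in LOWER_EYELIDS)
    width = lms.x(JAW_RIGHT) - x_left
    height = min(lms.y(i) for i in UPPER_LIP) - y_top
    if width <= 0 or height <= 0:
        raise DegenerateRoiError(
            f"frame {lms.frame_index}: degenerate cheek box (w={width}, h={height})"
        )
    return RoiBox(x_left, y_top, width, height)


def forehead_box(lms: LandmarkSet, cheek: RoiBox) -> RoiBox:
    """Forehead strip above the brows, half the cheek height tall."""
    x_left = lms.x(BROW_LEFT)
    width = lms.x(BROW_RIGHT) - x_left
    height = 0.5 * cheek.height
    y_top = min(lms.y(BROW_LEFT), lms.y(BROW_RIGHT)) - height
    if width <= 0:
        raise DegenerateRoiError(f"frame {lms.frame_index}: degenerate forehead box (w={width})")
    return RoiBox(x_left, y_top, width, height)


def _crop(frame: np.ndarray, box: RoiBox, clip_top: bool = False) -> np.ndarray:
    """Integer crop; fractional edges round to nearest."""
    H, W = frame.shape[:2]
    x0 = int(round(box.x_left))
    x1 = int(round(box.x_left + box.width))
    y0 = int(round(box.y_top))
    y1 = int(round(box.y_top + box.height))
    if y0 < 0 and clip_top:
        warnings.warn(f"box extends above the frame (y_top={box.y_top:.1f}); clipped to row 0",
                      stacklevel=3)
        y0 = 0
    x0c, x1c = max(x0, 0), min(x1, W)
    y0c, y1c = max(y0, 0), min(y1, H)
    if x1c <= x0c or y1c <= y0c:
        raise DegenerateRoiError(f"box {box} lies outside the {H}x{W} frame")
    return frame[y0c:y1c, x0c:x1c]


def crop_resize_stitch(
    frame: np.ndarray,
    cheek: RoiBox,
    forehead: RoiBox,
    out_size: tuple[int, int] = (96, 96),
) -> np.ndarray:
    """Crop both boxes, resize (bilinear) and stack cheek over forehead.

    The cheek occupies the top two thirds of the output, the forehead the
    bottom third; default output 96x96x3 (64x96 over 32x96), dtype uint8.
    """
    H, W = out_size
    if H % 3:
        raise ValueError(f"output height must be divisible by 3, got {H}")
    cheek_px = _crop(frame, cheek)
    forehead_px = _crop(frame, forehead, clip_top=True)
    ch = _resize(cheek_px.astype(np.float64), (2 * H // 3, W), order=1,
                 anti_aliasing=False, preserve_range=True)
    fh = _resize(forehead_px.astype(np.float64), (H // 3, W), order=1,
                 anti_aliasing=False, preserve_range=True)
    stitched = np.concatenate([ch, fh], axis=0)
    if np.issubdtype(frame.dtype, np.integer):
        return np.clip(np.rint(stitched), 0, 255).astype(frame.dtype)
    return stitched.astype(frame.dtype)


def build_clips(
    stitched: Sequence[np.ndarray] | np.ndarray,
    clip_len: int = 128,
    stride: int = 8,
    frame_rate: float = 30.0,
) -> list[RoiClip]:
    """Cut a stitched-frame sequence into overlapping clips.

    Clips start at 0, stride, 2*stride, ...; the count is
    ``floor((N - clip_len) / stride) + 1``.  Too-short input yields an
    empty list with a warning.
    """
    frames = np.asarray(stitched)
    n = frames.shape[0]
    if n < clip_len:
        warnings.warn(f"sequence of {n} frames shorter than clip_len={clip_len}; no clips")
        return []
    count = (n - clip_len) // stride + 1
    return [
        RoiClip(frames=frames[s : s + clip_len], start_frame=s, frame_rate=frame_rate)
        for s in (i * stride for i in range(count))
    ]
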