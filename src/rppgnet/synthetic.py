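"""Synthetic pulse-video generator.

Produces fully labeled scenes — frames, 68-point landmarks, and a 60 Hz
reference pulse — with the statistical structure the method assumes: a
face-like skin region whose color is additively modulated by a
quasi-periodic pulse waveform (green channel weighted twice red/blue),
per-pixel sensor noise, slow global illumination drift, static skin
texture, and landmark jitter.  Everything is a pure function of
(config, seed).

The generator does *not* attempt photo-realism: there is no head motion,
no specular highlights, no compression artifacts.  Its purpose is to make
every pipeline stage and the end-to-end learning loop testable without
recorded datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .hr_estimation import (
    DEFAULT_STEP_S,
    DEFAULT_WINDOW_S,
    HR_BAND_HZ,
    HrSeries,
    PulseTrace,
)
from .roi import LandmarkSet, write_landmarks

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "landmark_template",
    "pulse_waveform",
    "render_scene",
    "write_scene",
    "load_scene_config",
]

BPM_RANGE = (42.0, 150.0)
SKIN_BASE_RGB = (168.0, 124.0, 104.0)
BACKGROUND_GRAY = 52.0
PULSE_COLOR_VEC = (0.5, 1.0, 0.5)  # green carries twice the pulse of red/blue
SECOND_HARMONIC = 0.3
TEXTURE_SD = 2.0  # static per-pixel skin texture (intensity units)


@dataclass(frozen=True)
class SceneConfig:
    duration_s: float = 10.0
    frame_rate: float = 30.0
    frame_size: tuple[int, int] = (128, 128)  # (H, W)
    ppg_rate: float = 60.0
    # constant bpm, or breakpoints [(t_s, bpm), ...] linearly interpolated
    hr_trajectory: float | tuple[tuple[float, float], ...] = 72.0
    pulse_amplitude: float = 2.0
    noise_sd: float = 1.0
    illumination_drift_amp: float = 1.0
    illumination_drift_period_s: float = 20.0
    landmark_jitter_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        bpms = self.trajectory_bpm(np.array([0.0, self.duration_s]))
        lo, hi = float(np.min(bpms)), float(np.max(bpms))
        if lo < BPM_RANGE[0] or hi > BPM_RANGE[1]:
            raise ValueError(f"hr_trajectory [{lo}, {hi}] bpm outside {BPM_RANGE}")
        if self.pulse_amplitude < 0:
            raise ValueError("pulse_amplitude must be non-negative")
        if min(self.frame_size) < 64:
            raise ValueError(f"frame_size {self.frame_size} too small for the face layout")

    def trajectory_bpm(self, t: np.ndarray) -> np.ndarray:
        if np.isscalar(self.hr_trajectory):
            return np.full_like(np.asarray(t, dtype=np.float64), float(self.hr_trajectory))
        pts = np.asarray(self.hr_trajectory, dtype=np.float64)
        return np.interp(t, pts[:, 0], pts[:, 1])


@dataclass
class SyntheticScene:
    frames: np.ndarray  # (T, H, W, 3) uint8
    landmarks: list[LandmarkSet]
    reference: PulseTrace  # at ppg_rate
    true_hr: HrSeries
    skin_mask: np.ndarray  # (H, W) bool, for the spatial-mean baseline
    config: SceneConfig


def landmark_template(frame_size: tuple[int, int]) -> np.ndarray:
    """Canonical 68-point layout scaled to the frame (0-based convention).

    Jaw 0-16 along a lower half-ellipse, brows 17-26, nose 27-35, eyes
    36-47 (lower lids at 40/41 and 46/47), mouth 48-67 (upper-lip top at
    50/52).  Proportions are chosen so the cheek and forehead boxes land
    inside the skin ellipse and the forehead stays inside the frame.
    """
    H, W = frame_size
    cx, cy = W / 2.0, H * 0.53
    a, b = W * 0.33, H * 0.42  # face half-axes
    pts = np.zeros((68, 2))
    # jaw: left temple -> chin -> right temple (y-down)
    phi = np.pi + np.pi * np.arange(17) / 16.0
    pts[0:17, 0] = cx + a * np.cos(phi)
    pts[0:17, 1] = cy - b * np.sin(phi)
    # brows
    brow_y = cy - 0.55 * b
    pts[17:22, 0] = cx + a * np.linspace(-0.80, -0.20, 5)
    pts[17:22, 1] = brow_y + 0.03 * b * np.array([1, 0, -0.5, 0, 1])
    pts[22:27, 0] = cx + a * np.linspace(0.20, 0.80, 5)
    pts[22:27, 1] = brow_y + 0.03 * b * np.array([1, 0, -0.5, 0, 1])
    # nose bridge + base
    pts[27:31, 0] = cx
    pts[27:31, 1] = cy + b * np.linspace(-0.40, -0.05, 4)
    pts[31:36, 0] = cx + a * np.linspace(-0.15, 0.15, 5)
    pts[31:36, 1] = cy - 0.02 * b
    # eyes: hexagons, indices 3,4 (relative) are the lower lid
    for base, ex in ((36, cx - 0.45 * a), (42, cx + 0.45 * a)):
        ey = cy - 0.30 * b
        ew, eh = 0.16 * a, 0.05 * b
        hexagon = np.array([
            (-ew, 0.0), (-ew / 2, -eh), (ew / 2, -eh),
            (ew, 0.0), (ew / 2, eh), (-ew / 2, eh),
        ])
        pts[base : base + 6] = hexagon + (ex, ey)
    # mouth: outer 12, inner 8; 50/52 are the upper-lip top
    my = cy + 0.45 * b
    mw, mh = 0.35 * a, 0.10 * b
    ang = 2 * np.pi * np.arange(12) / 12.0
    pts[48:60, 0] = cx - mw * np.cos(ang)
    pts[48:60, 1] = my + mh * np.sin(ang) - mh * (np.cos(ang) ** 2) * 0.4
    pts[50, 1] = my - mh
    pts[52, 1] = my - mh
    ang8 = 2 * np.pi * np.arange(8) / 8.0
    pts[60:68, 0] = cx - 0.6 * mw * np.cos(ang8)
    pts[60:68, 1] = my + 0.5 * mh * np.sin(ang8)
    return pts


def _face_mask(frame_size: tuple[int, int]) -> np.ndarray:
    H, W = frame_size
    cx, cy = W / 2.0, H * 0.53
    a, b = W * 0.33, H * 0.42
    yy, xx = np.mgrid[0:H, 0:W]
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def pulse_waveform(
    hr_trajectory: float | tuple[tuple[float, float], ...],
    rate: float,
    duration_s: float,
    seed: int = 0,
) -> PulseTrace:
    """Quasi-periodic pulse surrogate: fundamental + 0.3x second harmonic.

    The instantaneous frequency follows the bpm trajectory (phase is the
    integral of frequency), so a constant trajectory gives a periodic
    waveform and a drifting one sweeps smoothly.  The seed fixes the
    initial phase.
    """
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    cfg = SceneConfig(duration_s=duration_s, hr_trajectory=hr_trajectory)
    freq_hz = cfg.trajectory_bpm(t) / 60.0
    phase0 = np.random.default_rng(seed).uniform(0, 2 * np.pi)
    phase = phase0 + 2 * np.pi * np.cumsum(freq_hz) / rate
    samples = np.sin(phase) + SECOND_HARMONIC * np.sin(2 * phase)
    return PulseTrace(samples=samples, rate=rate, t0=0.0)


def _true_hr_series(config: SceneConfig) -> HrSeries:
    starts = []
    s = 0.0
    while s + DEFAULT_WINDOW_S <= config.duration_s + 1e-9:
        starts.append(s)
        s += DEFAULT_STEP_S
    starts = np.asarray(starts)
    centers = starts + DEFAULT_WINDOW_S / 2.0
    return HrSeries(starts=starts, bpm=config.trajectory_bpm(centers))


def render_scene(config: SceneConfig) -> SyntheticScene:
    """Render frames + landmarks + reference trace for one scene."""
    rng = np.random.default_rng(config.seed)
    H, W = config.frame_size
    n_frames = int(round(config.duration_s * config.frame_rate))
    template = landmark_template(config.frame_size)
    mask = _face_mask(config.frame_size)

    reference = pulse_waveform(config.hr_trajectory, config.ppg_rate,
                               config.duration_s, seed=config.seed)
    frame_times = np.arange(n_frames) / config.frame_rate
    pulse_at_frames = np.interp(frame_times, reference.times(), reference.samples)

    base = np.full((H, W, 3), BACKGROUND_GRAY)
    base[mask] = SKIN_BASE_RGB
    base += rng.normal(0.0, TEXTURE_SD, size=(H, W, 3))  # static texture dithers quantization

    drift_phase = rng.uniform(0, 2 * np.pi)
    color_vec = np.asarray(PULSE_COLOR_VEC)

    frames = np.empty((n_frames, H, W, 3), dtype=np.uint8)
    landmarks = []
    for i in range(n_frames):
        img = base.copy()
        img[mask] += config.pulse_amplitude * pulse_at_frames[i] * color_vec
        if config.illumination_drift_amp > 0:
            img += config.illumination_drift_amp * np.sin(
                drift_phase + 2 * np.pi * frame_times[i] / config.illumination_drift_period_s
            )
        if config.noise_sd > 0:
            img += rng.normal(0.0, config.noise_sd, size=img.shape)
        frames[i] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        jitter = rng.normal(0.0, config.landmark_jitter_sd, size=(68, 2)) \
            if config.landmark_jitter_sd > 0 else 0.0
        landmarks.append(LandmarkSet(points=template + jitter, frame_index=i))

    return SyntheticScene(
        frames=frames,
        landmarks=landmarks,
        reference=reference,
        true_hr=_true_hr_series(config),
        skin_mask=mask,
        config=config,
    )


def write_scene(scene: SyntheticScene, out_dir: str | Path) -> None:
    """Persist a scene: PNG frames, landmark CSV, reference text, config YAML."""
    out = Path(out_dir)
    frames_dir = out / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(scene.frames):
        iio.imwrite(frames_dir / f"{i:06d}.png", frame)
    write_landmarks(scene.landmarks, out / "landmarks.csv")
    np.savetxt(out / "reference_ppg.txt", scene.reference.samples)
    cfg = asdict(scene.config)
    cfg["reference_rate_hz"] = scene.config.ppg_rate
    with open(out / "scene.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)


def load_scene_config(path: str | Path) -> SceneConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw.pop("reference_rate_hz", None)
    known = set(SceneConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown scene config keys: {sorted(unknown)}")
    for key in ("frame_size",):
        if key in raw:
            raw[key] = tuple(raw[key])
    if isinstance(raw.get("hr_trajectory"), list):
        raw["hr_trajectory"] = tuple(tuple(p) for p in raw["hr_trajectory"])
    return SceneConfig(**raw)
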