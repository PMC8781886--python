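"""Signal alignment, band-pass filtering, spectral HR extraction, metrics.

Heart rate is read off a pulse trace spectrally: the trace is band-passed
to the physiological band 0.7-2.5 Hz (42-150 bpm) with a zero-phase
sixth-order Butterworth filter, split into 10 s windows sliding by 2 s,
and each window's HR is 60x the frequency of the dominant power-spectrum
peak inside the band (mean-removed, Hann-windowed, zero-padded FFT so the
frequency grid is at most 0.01 Hz).

Agreement between predicted and reference HR series is summarized by MAE,
RMSE and Pearson's correlation over windows, plus a Bland-Altman table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "PulseTrace",
    "HrSeries",
    "MetricsReport",
    "resample_reference",
    "bandpass",
    "estimate_hr_window",
    "windowed_hr",
    "compute_metrics",
    "bland_altman_table",
    "HR_BAND_HZ",
]

HR_BAND_HZ = (0.7, 2.5)
DEFAULT_WINDOW_S = 10.0
DEFAULT_STEP_S = 2.0
MAX_FREQ_RESOLUTION_HZ = 0.01


class SignalTooShortError(ValueError):
    pass


class UndefinedHrError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


@dataclass
class PulseTrace:
    """Uniformly sampled 1-D signal: ``samples`` at ``rate`` Hz from ``t0`` s."""

    samples: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples in pulse trace")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.rate


@dataclass
class HrSeries:
    """Per-window HR estimates: ``starts`` (s), ``bpm``, window length/step (s)."""

    starts: np.ndarray
    bpm: np.ndarray
    window_len: float = DEFAULT_WINDOW_S
    step: float = DEFAULT_STEP_S

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.float64)
        self.bpm = np.asarray(self.bpm, dtype=np.float64)
        if self.starts.shape != self.bpm.shape:
            raise AlignmentError("starts and bpm must have equal length")

    def __len__(self) -> int:
        return len(self.bpm)


@dataclass
class MetricsReport:
    mae_bpm: float
    rmse_bpm: float
    pearson_r: float  # NaN when undefined (n < 2 or constant series)
    n_windows: int


def resample_reference(ppg: PulseTrace, frame_times: np.ndarray) -> PulseTrace:
    """Z-score the reference PPG, then linearly interpolate at frame times.

    The contact PPG (typically 60 Hz) and the video (typically 30 fps) run
    at different rates; the network's per-frame labels come from this
    alignment.  ``frame_times`` must be uniformly spaced and lie within
    the PPG time span.
    """
    frame_times = np.asarray(frame_times, dtype=np.float64)
    t = ppg.times()
    if frame_times.min() < t[0] - 1e-9 or frame_times.max() > t[-1] + 1e-9:
        bad = frame_times[(frame_times < t[0] - 1e-9) | (frame_times > t[-1] + 1e-9)][0]
        raise ValueError(f"frame time {bad:.4f}s outside reference span [{t[0]:.4f}, {t[-1]:.4f}]s")
    sd = ppg.samples.std()
    if sd == 0:
        warnings.warn("constant reference signal; normalized to all-zeros")
        z = np.zeros_like(ppg.samples)
    else:
        z = (ppg.samples - ppg.samples.mean()) / sd
    out = np.interp(frame_times, t, z)
    dt = np.diff(frame_times)
    rate = 1.0 / dt.mean() if len(dt) else ppg.rate
    return PulseTrace(samples=out, rate=rate, t0=float(frame_times[0]))


def bandpass(trace: PulseTrace, order: int = 6, band: tuple[float, float] = HR_BAND_HZ) -> PulseTrace:
    """Zero-phase Butterworth band-pass of the stated total order.

    Designed as an ``order/2``-section band-pass (a band-pass doubles the
    prototype order) and applied forward-backward so the output is not
    phase-shifted relative to the input; length is preserved.
    """
    if trace.rate <= 2 * band[1]:
        raise ValueError(f"rate {trace.rate} Hz too low for band up to {band[1]} Hz")
    if order % 2:
        raise ValueError(f"band-pass order must be even, got {order}")
    sos = sps.butter(order // 2, band, btype="bandpass", fs=trace.rate, output="sos")
    padlen = 3 * (2 * (order // 2) + 1)
    if len(trace.samples) <= padlen:
        raise SignalTooShortError(
            f"trace of {len(trace.samples)} samples too short for filter warm-up ({padlen})"
        )
    filtered = sps.sosfiltfilt(sos, trace.samples)
    return PulseTrace(samples=filtered, rate=trace.rate, t0=trace.t0)


def estimate_hr_window(window: PulseTrace, band: tuple[float, float] = HR_BAND_HZ) -> float:
    """HR (bpm) = 60x the in-band peak of the window's power spectrum.

    Mean-removed, Hann-windowed, zero-padded so the FFT grid is at most
    0.01 Hz.
    """
    x = window.samples
    if np.allclose(x, 0.0):
        raise UndefinedHrError("all-zero window has no spectral peak")
    x = (x - x.mean()) * np.hanning(len(x))
    nfft = 1 << int(np.ceil(np.log2(window.rate / MAX_FREQ_RESOLUTION_HZ)))
    nfft = max(nfft, len(x))
    spectrum = np.abs(np.fft.rfft(x, n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / window.rate)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any() or not np.any(spectrum[in_band] > 0):
        raise UndefinedHrError("no in-band spectral content")
    return float(60.0 * freqs[in_band][np.argmax(spectrum[in_band])])


def windowed_hr(
    trace: PulseTrace,
    window_len: float = DEFAULT_WINDOW_S,
    step: float = DEFAULT_STEP_S,
) -> HrSeries:
    """Sliding-window spectral HR; floor((duration - window)/step) + 1 windows."""
    n_win = int(round(window_len * trace.rate))
    n_step = int(round(step * trace.rate))
    n = len(trace.samples)
    if n < n_win:
        warnings.warn(f"trace of {trace.duration:.1f}s shorter than the {window_len:.0f}s window")
        return HrSeries(starts=np.array([]), bpm=np.array([]), window_len=window_len, step=step)
    starts, bpm = [], []
    for s in range(0, n - n_win + 1, n_step):
        seg = PulseTrace(samples=trace.samples[s : s + n_win], rate=trace.rate,
                         t0=trace.t0 + s / trace.rate)
        starts.append(seg.t0)
        bpm.append(estimate_hr_window(seg))
    return HrSeries(starts=np.array(starts), bpm=np.array(bpm), window_len=window_len, step=step)


def _check_aligned(pred: HrSeries, ref: HrSeries) -> None:
    if len(pred) != len(ref):
        raise AlignmentError(f"window counts differ: {len(pred)} vs {len(ref)}")
    if len(pred) and not np.allclose(pred.starts, ref.starts, atol=1e-6):
        raise AlignmentError("window start times differ between series")


def compute_metrics(pred: HrSeries, ref: HrSeries) -> MetricsReport:
    """MAE, RMSE and Pearson R over aligned per-window HR estimates."""
    _check_aligned(pred, ref)
    d = pred.bpm - ref.bpm
    mae = float(np.mean(np.abs(d)))
    rmse = float(np.sqrt(np.mean(d**2)))
    if len(d) < 2 or pred.bpm.std() == 0 or ref.bpm.std() == 0:
        warnings.warn("Pearson R undefined (fewer than 2 windows or a constant series)")
        r = float("nan")
    else:
        r = float(np.corrcoef(pred.bpm, ref.bpm)[0, 1])
    return MetricsReport(mae_bpm=mae, rmse_bpm=rmse, pearson_r=r, n_windows=len(d))


def bland_altman_table(pred: HrSeries, ref: HrSeries) -> tuple[pd.DataFrame, float, float, float]:
    """Per-window (mean, difference) rows plus bias and 1.96*SD limits."""
    _check_aligned(pred, ref)
    diff = pred.bpm - ref.bpm
    mean = (pred.bpm + ref.bpm) / 2.0
    table = pd.DataFrame({"start_s": pred.starts, "mean_bpm": mean, "diff_bpm": diff})
    bias = float(diff.mean())
    sd = float(diff.std(ddof=0))
    return table, bias, bias - 1.96 * sd, bias + 1.96 * sd
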