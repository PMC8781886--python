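import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rppgnet.hr_estimation import (
    AlignmentError,
    HrSeries,
    PulseTrace,
    SignalTooShortError,
    UndefinedHrError,
    bandpass,
    bland_altman_table,
    compute_metrics,
    estimate_hr_window,
    resample_reference,
    windowed_hr,
)


def sine_trace(freq_hz, duration_s, rate, amp=1.0):
    t = np.arange(int(duration_s * rate)) / rate
    return PulseTrace(samples=amp * np.sin(2 * np.pi * freq_hz * t), rate=rate)


class TestResampleReference:
    def test_coincident_times_reproduce_zscored_samples(self):
        ppg = PulseTrace(samples=np.arange(60.0), rate=60.0)
        frame_times = np.arange(30) / 30.0
        out = resample_reference(ppg, frame_times)
        z = (np.arange(60.0) - np.arange(60.0).mean()) / np.arange(60.0).std()
        np.testing.assert_allclose(out.samples, z[::2], atol=1e-12)
        assert out.rate == pytest.approx(30.0)

    def test_constant_signal_warns_and_zeroes(self):
        ppg = PulseTrace(samples=np.full(100, 4.2), rate=60.0)
        with pytest.warns(UserWarning, match="constant"):
            out = resample_reference(ppg, np.arange(30) / 30.0)
        np.testing.assert_array_equal(out.samples, 0.0)

    def test_frequency_content_preserved_below_nyquist(self):
        src = sine_trace(1.2, 20.0, 60.0)
        frame_times = np.arange(int(20 * 30) - 1) / 30.0
        out = resample_reference(src, frame_times)
        assert estimate_hr_window(
            PulseTrace(out.samples[:300], rate=30.0)
        ) == pytest.approx(72.0, abs=0.5)

    def test_out_of_span_time_rejected(self):
        ppg = PulseTrace(samples=np.arange(60.0), rate=60.0)
        with pytest.raises(ValueError, match="outside"):
            resample_reference(ppg, np.array([0.5, 1.5]))


class TestBandpass:
    def test_dc_removed(self):
        trace = PulseTrace(samples=np.full(300, 5.0), rate=30.0)
        out = bandpass(trace)
        assert np.abs(out.samples).max() < 1e-6 * 5.0

    def test_passband_amplitude_preserved(self):
        out = bandpass(sine_trace(1.2, 20.0, 30.0))
        mid = out.samples[150:-150]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuated_20db(self):
        out = bandpass(sine_trace(5.0, 20.0, 30.0))
        assert np.abs(out.samples[150:-150]).max() < 0.1  # > 20 dB down

    def test_idempotent_on_in_band_sine(self):
        once = bandpass(sine_trace(1.5, 20.0, 30.0))
        twice = bandpass(once)
        mid = slice(150, -150)
        ratio = np.abs(twice.samples[mid]).max() / np.abs(once.samples[mid]).max()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_too_short_signal_raises(self):
        with pytest.raises(SignalTooShortError):
            bandpass(PulseTrace(samples=np.zeros(10), rate=30.0))

    def test_length_preserved(self):
        out = bandpass(sine_trace(1.0, 15.0, 30.0))
        assert len(out.samples) == 450


class TestSpectralHr:
    @pytest.mark.parametrize("bpm", [42.0, 60.0, 72.0, 96.5, 120.0, 150.0])
    def test_clean_sine_recovered_within_a_bin(self, bpm):
        trace = sine_trace(bpm / 60.0, 10.0, 30.0)
        bin_bpm = 60.0 * 30.0 / 4096  # rate / nfft
        assert estimate_hr_window(trace) == pytest.approx(bpm, abs=bin_bpm)

    def test_dominant_peak_wins(self):
        t = np.arange(300) / 30.0
        mix = 3.0 * np.sin(2 * np.pi * 1.0 * t) + 0.5 * np.sin(2 * np.pi * 2.0 * t)
        assert estimate_hr_window(PulseTrace(samples=mix, rate=30.0)) == pytest.approx(60.0, abs=0.5)

    def test_all_zero_window_rejected(self):
        with pytest.raises(UndefinedHrError):
            estimate_hr_window(PulseTrace(samples=np.zeros(300), rate=30.0))


class TestWindowedHr:
    @pytest.mark.parametrize("duration,expected", [
        (30.0, 11), (10.0, 1), (12.0, 2), (120.0, 56), (11.9, 1),
    ])
    def test_window_count_closed_form(self, duration, expected):
        series = windowed_hr(sine_trace(1.2, duration, 30.0))
        assert len(series) == expected == int((duration - 10) // 2) + 1

    def test_too_short_trace_warns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            series = windowed_hr(sine_trace(1.2, 8.0, 30.0))
        assert len(series) == 0

    def test_frequency_step_tracked(self):
        # 72 bpm for 15 s then 96 bpm: early windows near 72, late near 96
        rate = 30.0
        t1 = np.arange(int(15 * rate)) / rate
        phase1 = 2 * np.pi * 1.2 * t1
        t2 = np.arange(int(15 * rate)) / rate
        phase2 = phase1[-1] + 2 * np.pi * 1.6 * t2
        trace = PulseTrace(samples=np.sin(np.concatenate([phase1, phase2])), rate=rate)
        series = windowed_hr(trace)
        assert series.bpm[0] == pytest.approx(72.0, abs=1.0)
        assert series.bpm[-1] == pytest.approx(96.0, abs=1.0)


def _series(bpm, start=0.0):
    bpm = np.asarray(bpm, dtype=float)
    return HrSeries(starts=start + 2.0 * np.arange(len(bpm)), bpm=bpm)


class TestMetrics:
    def test_identical_series(self):
        with pytest.warns(UserWarning, match="undefined"):
            rep = compute_metrics(_series([72, 72]), _series([72, 72]))
        assert rep.mae_bpm == rep.rmse_bpm == 0.0
        assert np.isnan(rep.pearson_r)

    def test_hand_example(self):
        rep = compute_metrics(_series([72, 80, 60]), _series([70, 80, 64]))
        assert rep.mae_bpm == pytest.approx(2.0)
        assert rep.rmse_bpm == pytest.approx(np.sqrt(20 / 3), abs=1e-9)
        assert rep.pearson_r == pytest.approx(0.9667, abs=1e-3)
        assert rep.n_windows == 3

    def test_single_window_r_is_nan(self):
        with pytest.warns(UserWarning, match="undefined"):
            rep = compute_metrics(_series([75]), _series([70]))
        assert rep.mae_bpm == rep.rmse_bpm == 5.0
        assert np.isnan(rep.pearson_r)

    def test_misaligned_series_rejected(self):
        with pytest.raises(AlignmentError):
            compute_metrics(_series([72, 80]), _series([70, 80, 64]))
        with pytest.raises(AlignmentError):
            compute_metrics(_series([72, 80]), _series([70, 80], start=1.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(42, 150), min_size=2, max_size=20), st.data())
    def test_rmse_at_least_mae(self, pred, data):
        ref = data.draw(st.lists(st.floats(42, 150), min_size=len(pred), max_size=len(pred)))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = compute_metrics(_series(pred), _series(ref))
        assert rep.rmse_bpm >= rep.mae_bpm - 1e-12


class TestBlandAltman:
    def test_identical_series_zero_limits(self):
        table, bias, lo, hi = bland_altman_table(_series([70, 80, 90]), _series([70, 80, 90]))
        assert np.all(table["diff_bpm"] == 0)
        assert bias == lo == hi == 0.0

    def test_constant_offset(self):
        table, bias, lo, hi = bland_altman_table(_series([75, 85, 95]), _series([70, 80, 90]))
        assert bias == pytest.approx(5.0)
        assert lo == pytest.approx(5.0)
        assert hi == pytest.approx(5.0)

    def test_row_count_matches_windows(self, rng):
        pred = _series(rng.uniform(50, 120, 9))
        ref = _series(rng.uniform(50, 120, 9))
        table, *_ = bland_altman_table(pred, ref)
        assert len(table) == 9
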