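import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cuffsim.hr_pipeline import (
    BPMSeries,
    PeakSeries,
    WatchModel,
    bpm_series,
    find_peaks_offline,
    load_watch_models,
    smooth,
    watch_display,
)
from cuffsim.signal_model import PPGTrace, SubjectProfile, generate_beat_times, render_ppg

from conftest import FS


def brute_force_peaks(values, height, distance):
    """Independent oracle: enumerate local maxima above height, then
    repeatedly keep the tallest remaining (earlier index on ties) and
    discard conflicts."""
    cand = [
        i
        for i in range(1, len(values) - 1)
        if values[i] > values[i - 1] and values[i] > values[i + 1] and values[i] > height
    ]
    kept = []
    remaining = set(cand)
    while remaining:
        best = min(remaining, key=lambda i: (-values[i], i))
        kept.append(best)
        remaining = {i for i in remaining if abs(i - best) >= distance}
    return sorted(kept)


class TestSmooth:
    def test_constant_trace_unchanged(self):
        trace = PPGTrace(np.full(500, 123.0), fs_hz=FS)
        np.testing.assert_allclose(smooth(trace).values, 123.0)

    def test_impulse_response_is_mean_kernel(self):
        v = np.zeros(201)
        v[100] = 1.0
        sm = smooth(PPGTrace(v, fs_hz=FS)).values
        np.testing.assert_allclose(sm[80:121], 1.0 / 41.0)
        assert sm[79] == 0.0 and sm[121] == 0.0

    def test_boundaries_use_truncated_window(self):
        v = np.ones(100)
        v[0] = 42.0
        sm = smooth(PPGTrace(v, fs_hz=FS)).values
        assert sm[0] == pytest.approx((42.0 + 20.0) / 21.0)  # 21-sample edge window

    def test_linearity_superposition(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=400), rng.normal(size=400)
        sa = smooth(PPGTrace(a + 100, fs_hz=FS)).values
        sb = smooth(PPGTrace(b + 100, fs_hz=FS)).values
        sab = smooth(PPGTrace(a + b + 200, fs_hz=FS)).values
        np.testing.assert_allclose(sab, sa + sb, atol=1e-9)

    @pytest.mark.parametrize("window", [0, -3, 40])
    def test_bad_window_rejected(self, window):
        with pytest.raises(ValueError):
            smooth(PPGTrace(np.ones(100), fs_hz=FS), window=window)

    def test_noisy_peaks_shift_less_than_25_ms(self, template):
        subject = SubjectProfile(true_hr_bpm=60.0, noise_sd_counts=8.0)
        clean_subject = SubjectProfile(true_hr_bpm=60.0, noise_sd_counts=0.0)
        beats = generate_beat_times(30.0, 60.0)
        noisy = render_ppg(beats, template, subject, duration_s=30.0, seed=2)
        clean = render_ppg(beats, template, clean_subject, duration_s=30.0)
        p_noisy = find_peaks_offline(smooth(noisy)).peak_times_s
        p_clean = find_peaks_offline(smooth(clean)).peak_times_s
        assert len(p_noisy) == len(p_clean)
        assert np.max(np.abs(p_noisy - p_clean)) < 0.025


class TestFindPeaksOffline:
    def test_noiseless_trace_matches_beat_count(self, template):
        subject = SubjectProfile(true_hr_bpm=60.0, noise_sd_counts=0.0)
        beats = generate_beat_times(120.0, 60.0)
        sm = smooth(render_ppg(beats, template, subject, duration_s=120.0))
        peaks = find_peaks_offline(sm)
        assert len(peaks) == 120

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # band-limited random signal so local maxima are well separated
        v = np.convolve(rng.normal(size=4000), np.ones(25) / 25, mode="same")
        trace = PPGTrace(v + 10.0, fs_hz=FS)
        for distance in (30, 100):
            ours = find_peaks_offline(trace, distance_samples=distance)
            oracle = brute_force_peaks(trace.values, float(np.mean(trace.values)), distance)
            np.testing.assert_allclose(ours.peak_times_s * FS, oracle)

    def test_all_below_height_empty(self):
        trace = PPGTrace(np.sin(np.arange(1000) / 30.0) + 100.0, fs_hz=FS)
        assert len(find_peaks_offline(trace, height=200.0)) == 0

    def test_equal_maxima_tie_breaks_to_earlier(self):
        v = np.zeros(300)
        v[100] = 5.0
        v[160] = 5.0  # 60 samples apart, equal height
        peaks = find_peaks_offline(PPGTrace(v, fs_hz=FS), height=1.0, distance_samples=100)
        np.testing.assert_allclose(peaks.peak_times_s, [100 / FS])

    def test_larger_peak_wins_conflict(self):
        v = np.zeros(300)
        v[100] = 5.0
        v[160] = 7.0
        peaks = find_peaks_offline(PPGTrace(v, fs_hz=FS), height=1.0, distance_samples=100)
        np.testing.assert_allclose(peaks.peak_times_s, [160 / FS])

    def test_invalid_distance(self):
        with pytest.raises(ValueError):
            find_peaks_offline(PPGTrace(np.ones(10), fs_hz=FS), distance_samples=0)


class TestBPMSeries:
    def test_one_second_intervals_give_sixty(self):
        peaks = PeakSeries(np.arange(0.0, 21.0))
        series = bpm_series(peaks, 20.0)
        defined = series.bpm[np.isfinite(series.bpm)]
        np.testing.assert_allclose(defined, 60.0)

    def test_three_quarter_second_intervals_give_eighty(self):
        peaks = PeakSeries(np.arange(0.0, 15.0, 0.75))
        series = bpm_series(peaks, 14.0)
        assert series.bpm[-1] == pytest.approx(80.0)

    def test_window_flushes_to_new_rate(self):
        # 5 intervals of 1.0 s then 10 of 0.5 s: once the 10-interval
        # window holds only the fast intervals the estimate is 120
        times = np.concatenate([np.arange(0.0, 6.0), 5.0 + 0.5 * np.arange(1, 11)])
        series = bpm_series(PeakSeries(times), 12.0)
        assert series.bpm[-1] == pytest.approx(120.0)

    def test_undefined_before_first_interval(self):
        series = bpm_series(PeakSeries(np.array([5.0, 6.0])), 10.0)
        assert np.all(np.isnan(series.bpm[:6]))
        np.testing.assert_allclose(series.bpm[6:], 60.0)

    def test_fewer_than_two_peaks_all_undefined(self):
        series = bpm_series(PeakSeries(np.array([3.0])), 10.0)
        assert np.all(np.isnan(series.bpm))

    @given(c=st.floats(0.5, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_interval_scaling_scales_bpm_inversely(self, c):
        base = np.arange(0.0, 15.0, 0.8)
        fast = bpm_series(PeakSeries(base), 14.0)
        scaled = bpm_series(PeakSeries(base * c), 14.0 * c)
        f = fast.bpm[np.isfinite(fast.bpm)][-1]
        s = scaled.bpm[np.isfinite(scaled.bpm)][-1]
        assert s == pytest.approx(f / c, rel=1e-9)


@pytest.fixture(scope="module")
def watches():
    return load_watch_models()


class TestWatchDisplay:
    def test_published_limits(self, watches):
        assert (watches["fitbit"].min_display, watches["fitbit"].max_display) == (54, 201)
        assert (watches["apple"].min_display, watches["apple"].max_display) == (44, 210)
        assert (watches["garmin"].min_display, watches["garmin"].max_display) == (45, 189)
        assert (watches["paenoon"].min_display, watches["paenoon"].max_display) == (48, 180)

    def test_clamp_floor_and_ceiling(self, watches):
        series = BPMSeries(np.array([0.0, 1.0, 2.0]), np.array([30.0, 220.0, 80.0]))
        garmin = watch_display(series, watches["garmin"])
        np.testing.assert_allclose(garmin.bpm, [45.0, 189.0, 80.0])
        apple = watch_display(series, watches["apple"])
        np.testing.assert_allclose(apple.bpm, [44.0, 210.0, 80.0])

    def test_in_range_identity_and_none_watch(self, watches):
        series = BPMSeries(np.array([0.0, 1.0]), np.array([70.0, 100.0]))
        np.testing.assert_allclose(watch_display(series, watches["fitbit"]).bpm, [70.0, 100.0])
        np.testing.assert_allclose(watch_display(series, None).bpm, [70.0, 100.0])

    def test_dropout_blanks_instead_of_clamping(self):
        watch = WatchModel(name="x", min_display=45, max_display=189, dropout=True)
        series = BPMSeries(np.array([0.0, 1.0]), np.array([30.0, 80.0]))
        out = watch_display(series, watch)
        assert np.isnan(out.bpm[0]) and out.bpm[1] == 80.0

    def test_invalid_limits(self):
        with pytest.raises(ValueError):
            WatchModel(name="bad", min_display=100, max_display=50)


def test_end_to_end_unattacked_pipeline_within_one_bpm(template):
    """Noiseless 80 bpm trace through smooth + peaks + interval
    averaging settles within 1 bpm of the true rate from t = 15 s."""
    subject = SubjectProfile(true_hr_bpm=80.0, noise_sd_counts=0.0)
    beats = generate_beat_times(60.0, 80.0)
    trace = render_ppg(beats, template, subject, duration_s=60.0)
    series = bpm_series(find_peaks_offline(smooth(trace)), 60.0)
    late = series.bpm[series.times_s >= 15.0]
    assert np.all(np.abs(late - 80.0) <= 1.0)
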