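import numpy as np
import pytest

from cuffsim.signal_model import (
    BeatTemplate,
    PPGTrace,
    SubjectProfile,
    generate_beat_times,
    occlusion_attenuation,
    render_ppg,
)

from conftest import FS, local_maxima


class TestBeatTimes:
    def test_zero_jitter_is_a_regular_grid(self):
        onsets = generate_beat_times(10.0, 60.0, 0.0, seed=5)
        np.testing.assert_allclose(onsets, np.arange(10.0), atol=1e-9)

    def test_beat_count_matches_rate(self):
        assert len(generate_beat_times(60.0, 80.0, 0.0)) == 80

    def test_jittered_mean_interval_converges(self):
        onsets = generate_beat_times(600.0, 70.0, 0.02, seed=1)
        mean_ibi = np.mean(np.diff(onsets))
        assert abs(mean_ibi - 60.0 / 70.0) / (60.0 / 70.0) < 0.01

    def test_strictly_increasing_and_reproducible(self):
        a = generate_beat_times(120.0, 100.0, 0.05, seed=7)
        b = generate_beat_times(120.0, 100.0, 0.05, seed=7)
        np.testing.assert_array_equal(a, b)
        assert np.all(np.diff(a) > 0)

    @pytest.mark.parametrize("duration,hr", [(0.0, 60.0), (-1.0, 60.0), (10.0, 0.0), (10.0, -5.0)])
    def test_invalid_parameters_rejected(self, duration, hr):
        with pytest.raises(ValueError):
            generate_beat_times(duration, hr)


class TestOcclusionAttenuation:
    def test_unoccluded_limit(self):
        assert occlusion_attenuation(0.0, 300.0, 20.0) >= 0.99

    def test_fully_occluded_limit(self):
        assert occlusion_attenuation(400.0, 300.0, 20.0) < 0.01
        assert occlusion_attenuation(300.0 + 3 * 20.0, 300.0, 20.0) < 0.01

    def test_monotone_non_increasing_on_grid(self):
        grid = np.arange(0.0, 451.0, 10.0)
        factors = occlusion_attenuation(grid, 300.0, 20.0)
        assert np.all(np.diff(factors) <= 0)
        assert np.all((factors >= 0) & (factors <= 1))

    def test_negative_pressure_clamps_to_vented(self):
        assert occlusion_attenuation(-50.0, 300.0, 20.0) == occlusion_attenuation(0.0, 300.0, 20.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            occlusion_attenuation(100.0, -1.0, 20.0)
        with pytest.raises(ValueError):
            occlusion_attenuation(100.0, 300.0, 0.0)


class TestRenderPPG:
    def test_single_beat_peak_height_and_phase(self, template, quiet_subject):
        trace = render_ppg(np.array([1.0]), template, quiet_subject, duration_s=3.0)
        expected_peak_t = 1.0 + template.peak_fraction * (60.0 / quiet_subject.true_hr_bpm)
        i = int(np.argmax(trace.values))
        assert abs(i / FS - expected_peak_t) <= 1.0 / FS
        assert trace.values[i] == pytest.approx(
            quiet_subject.baseline_counts + quiet_subject.amplitude_counts, rel=1e-3
        )

    def test_full_suppression_leaves_baseline(self, template, quiet_subject):
        beats = generate_beat_times(5.0, 80.0)
        trace = render_ppg(beats, template, quiet_subject, duration_s=5.0, attenuation=0.0)
        np.testing.assert_allclose(trace.values, quiet_subject.baseline_counts)

    def test_one_local_maximum_per_beat(self, template):
        subject = SubjectProfile(true_hr_bpm=60.0, noise_sd_counts=0.0)
        beats = generate_beat_times(10.0, 60.0)
        trace = render_ppg(beats, template, subject, duration_s=10.0)
        peaks = local_maxima(trace.values, subject.baseline_counts + 0.5 * subject.amplitude_counts)
        assert len(peaks) == len(beats) == 10
        # recovered peak times match beat time + template peak phase to a sample
        for i, onset in zip(peaks, beats):
            assert abs(i / FS - (onset + template.peak_fraction * 1.0)) <= 1.0 / FS

    def test_amplitude_scales_with_attenuation(self, template, quiet_subject):
        beats = np.array([1.0])
        full = render_ppg(beats, template, quiet_subject, duration_s=3.0)
        half = render_ppg(beats, template, quiet_subject, duration_s=3.0, attenuation=0.5)
        assert (half.values.max() - quiet_subject.baseline_counts) == pytest.approx(
            0.5 * (full.values.max() - quiet_subject.baseline_counts), rel=1e-6
        )

    def test_noise_reproducible_for_seed(self, template):
        subject = SubjectProfile(noise_sd_counts=5.0)
        beats = generate_beat_times(5.0, 80.0)
        a = render_ppg(beats, template, subject, duration_s=5.0, seed=9)
        b = render_ppg(beats, template, subject, duration_s=5.0, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_attenuation_length_mismatch_rejected(self, template, quiet_subject):
        with pytest.raises(ValueError):
            render_ppg(np.array([1.0]), template, quiet_subject, duration_s=3.0, attenuation=np.ones(5))


class TestTemplateAndTypes:
    def test_raised_cosine_satisfies_invariants(self, template):
        s = template.samples
        assert s.max() == pytest.approx(1.0)
        assert s.min() >= 0.0
        assert s[0] < 0.05 and s[-1] < 0.05
        assert template.peak_fraction == pytest.approx(0.25)

    def test_bad_template_rejected(self):
        with pytest.raises(ValueError):
            BeatTemplate(samples=np.array([0.5, 1.0, 0.5]))  # edges not near baseline
        with pytest.raises(ValueError):
            BeatTemplate(samples=np.array([0.0, 2.0, 0.0]))  # peak above 1

    def test_subject_profile_validation(self):
        with pytest.raises(ValueError):
            SubjectProfile(true_hr_bpm=0.0)
        with pytest.raises(ValueError):
            SubjectProfile(noise_sd_counts=-1.0)

    def test_trace_validation(self):
        with pytest.raises(ValueError):
            PPGTrace(np.array([1.0, np.nan]), fs_hz=200.0)
        with pytest.raises(ValueError):
            PPGTrace(np.array([]), fs_hz=200.0)
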