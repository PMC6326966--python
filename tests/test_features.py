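"""Acoustic measurements: pitch tracking, f0 summary, HNR, formants, ΔF."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coo_id.features import (
    ExtractionError,
    FormantConfig,
    PitchConfig,
    PitchContour,
    compute_hnr,
    estimate_delta_f,
    extract_features,
    extract_formants,
    extract_pitch,
    measure_duration,
    summarize_f0,
)
from coo_id.synth import CallRecording, IndividualProfile, synthesize_call

RATE = 44100


def _sine(freq, duration=1.0, rate=RATE, amp=0.8):
    t = np.arange(int(duration * rate)) / rate
    return CallRecording(amp * np.sin(2 * np.pi * freq * t), rate, "syn", f"sine{freq}")


def _white_noise(duration=1.0, rate=RATE, seed=0):
    rng = np.random.default_rng(seed)
    return CallRecording(0.9 * rng.uniform(-1, 1, int(duration * rate)),
                         rate, "syn", "noise")


class TestExtractPitch:
    def test_pure_sine_within_one_percent(self):
        contour = extract_pitch(_sine(200.0))
        assert np.mean(contour.voiced_f0) == pytest.approx(200.0, rel=0.01)

    def test_flat_synthetic_call_all_frames_within_two_percent(self, flat_call):
        contour = extract_pitch(flat_call)
        true_f0 = flat_call.true_params["true_mean_f0"]
        assert np.all(np.abs(contour.voiced_f0 - true_f0) / true_f0 < 0.02)

    def test_white_noise_mostly_unvoiced(self):
        try:
            contour = extract_pitch(_white_noise())
            assert contour.voiced_mask.mean() <= 0.1
        except ExtractionError:
            pass  # fully unvoiced is an acceptable outcome for noise

    def test_too_short_recording_rejected(self):
        with pytest.raises(ExtractionError, match="short"):
            extract_pitch(_sine(200.0, duration=0.02))

    def test_voiced_f0_inside_configured_window(self, flat_call):
        cfg = PitchConfig(pitch_floor=75, pitch_ceiling=1200)
        contour = extract_pitch(flat_call, cfg)
        v = contour.voiced_f0
        assert v.min() >= 75 and v.max() <= 1200


class TestSummarizeF0:
    @staticmethod
    def _contour(f0_values, voiced=None, step=0.01):
        f0 = np.asarray(f0_values, dtype=float)
        voiced = np.ones(f0.size, bool) if voiced is None else np.asarray(voiced)
        times = np.arange(f0.size) * step
        return PitchContour(times, f0, voiced, step)

    def test_constant_contour(self):
        s = summarize_f0(self._contour([250, 250, 250]))
        assert s["mean_f0"] == 250 and s["sd_f0"] == 0
        assert s["range_f0"] == 0 and s["start_f0"] == s["end_f0"] == 250

    def test_hand_computed_statistics(self):
        """[100, 150, 200]: mean 150, sample SD 50, range 100."""
        s = summarize_f0(self._contour([100, 150, 200]))
        assert s["mean_f0"] == pytest.approx(150)
        assert s["sd_f0"] == pytest.approx(50)
        assert s["min_f0"] == 100 and s["max_f0"] == 200
        assert s["range_f0"] == pytest.approx(100)
        assert s["start_f0"] == 100 and s["end_f0"] == 200

    def test_unvoiced_frames_are_masked(self):
        c = self._contour([100, 999, 999, 200], voiced=[True, False, False, True])
        s = summarize_f0(c)
        assert s["max_f0"] == 200 and s["mean_f0"] == pytest.approx(150)

    def test_fewer_than_two_voiced_frames_rejected(self):
        with pytest.raises(ExtractionError):
            summarize_f0(self._contour([100, 200], voiced=[True, False]))


class TestMeasureDuration:
    def test_recovers_synthesized_duration(self, flat_call):
        contour = extract_pitch(flat_call)
        assert measure_duration(contour) == pytest.approx(
            flat_call.true_params["true_duration"], abs=0.05)

    def test_single_voiced_frame_gives_one_step(self):
        c = PitchContour(np.array([0.0, 0.01, 0.02]),
                         np.array([np.nan, 300.0, np.nan]),
                         np.array([False, True, False]), 0.01)
        assert measure_duration(c) == pytest.approx(0.01)

    def test_silence_padding_invariance(self, flat_call):
        base = measure_duration(extract_pitch(flat_call))
        pad = np.zeros(int(0.5 * flat_call.rate))
        padded = CallRecording(np.concatenate([pad, flat_call.samples, pad]),
                               flat_call.rate, "syn", "padded")
        # edge resolution is one cross-correlation analysis window (~27 ms)
        # per side, so padding may extend the voiced span by up to ~2 windows
        assert measure_duration(extract_pitch(padded)) == pytest.approx(base, abs=0.055)


class TestFormants:
    def test_recovers_uniform_tube_formants_within_five_percent(self):
        """17.5 cm tube, 180 Hz flat source: estimated means within 5% of
        500/1500/2500/3500 Hz."""
        p = IndividualProfile("A", mean_f0=180, f0_within_sd=0,
                              f0_contour_shape="arc", vocal_tract_length=17.5,
                              mean_duration=0.6, duration_within_cv=0,
                              noise_gain=0.0)
        rec = synthesize_call(p, call_seed=3, rate=44100)
        means, _ = extract_formants(rec)
        np.testing.assert_allclose(means, [500, 1500, 2500, 3500], rtol=0.05)

    def test_delta_f_ordering_tracks_tract_length(self):
        """Shorter vocal tract, wider dispersion: measured ΔF must preserve
        the c/2L ordering between a 16 cm and a 20 cm tract."""
        est = {}
        # long tracts pack six resonances below 8 kHz, so the analysis is run
        # with a matching six-formant budget
        cfg = FormantConfig(max_n_formants=6)
        for vtl in (16.0, 20.0):
            p = IndividualProfile("A", mean_f0=150, f0_within_sd=0,
                                  f0_contour_shape="arc", vocal_tract_length=vtl,
                                  mean_duration=0.6, duration_within_cv=0,
                                  noise_gain=0.0)
            rec = synthesize_call(p, call_seed=4, rate=44100)
            means, _ = extract_formants(rec, cfg)
            est[vtl] = estimate_delta_f(means)
        assert est[16.0] > est[20.0]

    def test_white_noise_has_no_stable_formants(self):
        """Noise has no resonant structure: either a formant-failure error or
        visibly unstable per-frame tracks."""
        try:
            _, track = extract_formants(_white_noise(duration=0.3))
        except ExtractionError:
            return
        assert np.any(np.nanstd(track, axis=0) > 200.0)

    def test_max_formant_above_nyquist_rejected(self):
        rec = _sine(200, duration=0.3, rate=11025)
        with pytest.raises(ValueError, match="Nyquist"):
            extract_formants(rec, FormantConfig(max_formant=8000))


class TestDeltaF:
    def test_exact_uniform_tube_spacing(self):
        assert estimate_delta_f([500, 1500, 2500, 3500]) == pytest.approx(1000.0)

    def test_matches_zero_intercept_least_squares_oracle(self):
        """Brute-force normal-equation solution on a perturbed spacing."""
        F = np.array([550.0, 1450.0, 2550.0, 3450.0])
        x = np.array([0.5, 1.5, 2.5, 3.5])
        oracle = np.linalg.lstsq(x[:, None], F, rcond=None)[0][0]
        assert estimate_delta_f(F) == pytest.approx(oracle, rel=1e-12)

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=30, deadline=None)
    def test_linearity_in_scale(self, a):
        scaled = a * np.array([500.0, 1500.0, 2500.0, 3500.0])
        assert estimate_delta_f(scaled) == pytest.approx(a * 1000.0, rel=1e-9)

    def test_non_increasing_formants_rejected(self):
        with pytest.raises(ValueError):
            estimate_delta_f([1500, 500, 2500, 3500])


class TestHnr:
    def test_noiseless_periodic_call_at_least_30_db(self, flat_call):
        assert compute_hnr(flat_call) >= 30.0

    def test_white_noise_at_most_0_db(self):
        assert compute_hnr(_white_noise()) <= 0.0

    def test_known_mixture_near_closed_form(self):
        """Sine + noise at 99:1 power: frame r ≈ 0.99, so HNR ≈ 20 dB."""
        rng = np.random.default_rng(12)
        t = np.arange(RATE) / RATE
        harmonic = np.sin(2 * np.pi * 250 * t)
        noise = rng.standard_normal(RATE)
        noise *= np.sqrt(np.mean(harmonic**2) / 99.0 / np.mean(noise**2))
        x = harmonic + noise
        rec = CallRecording(0.9 * x / np.max(np.abs(x)), RATE, "syn", "mix")
        expected = 10 * np.log10(0.99 / 0.01)
        assert compute_hnr(rec) == pytest.approx(expected, abs=1.5)

    def test_hnr_decreases_with_noise_gain(self):
        base = dict(individual_id="A", mean_f0=340, f0_within_sd=0,
                    vocal_tract_length=9.6, mean_duration=0.4,
                    duration_within_cv=0)
        hnrs = [
            compute_hnr(synthesize_call(
                IndividualProfile(**base, noise_gain=g), 7, RATE))
            for g in (0.0, 0.05, 0.15, 0.4)
        ]
        assert all(np.diff(hnrs) < 0)


class TestExtractFeatures:
    def test_range_identity_and_ordering(self, flat_call):
        f = extract_features(flat_call)
        assert f.range_f0 == f.max_f0 - f.min_f0
        assert f.min_f0 <= f.mean_f0 <= f.max_f0
        assert f.min_f0 <= f.start_f0 <= f.max_f0
        assert f.min_f0 <= f.end_f0 <= f.max_f0
        assert 0 < f.F1 < f.F2 < f.F3 < f.F4
        assert f.duration > 0

    def test_matches_synthesis_ground_truth(self, flat_call):
        f = extract_features(flat_call)
        tp = flat_call.true_params
        assert f.mean_f0 == pytest.approx(tp["true_mean_f0"], rel=0.02)
        assert f.delta_f == pytest.approx(tp["true_deltaF"], rel=0.05)
        assert f.duration == pytest.approx(tp["true_duration"], rel=0.10)

    def test_deterministic_across_runs(self, flat_call):
        a = extract_features(flat_call)
        b = extract_features(flat_call)
        assert a == b

    def test_error_names_the_call(self):
        bad = _white_noise(duration=0.3, seed=5)
        bad.call_id = "badcall_007"
        with pytest.raises(ExtractionError, match="badcall_007"):
            extract_features(bad)


class TestRecoveryAtScale:
    def test_median_relative_errors_on_reference_dataset(self, paper_like_dataset):
        """Over 7 individuals / 162 calls: median relative extraction error
        below 2% for mean f0, 5% for F1-F4 and ΔF, 10% for duration."""
        features, truth = paper_like_dataset
        m = features.merge(truth, on="call_id")
        def med(col, true_col):
            return np.median(np.abs(m[col] - m[true_col]) / m[true_col])
        assert med("mean_f0", "true_mean_f0") < 0.02
        for k in range(1, 5):
            assert med(f"F{k}", f"true_F{k}") < 0.05, f"F{k}"
        assert med("delta_f", "true_deltaF") < 0.05
        assert med("duration", "true_duration") < 0.10
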