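import numpy as np
import pytest

from ppgage import (
    CohortSpec,
    ParameterError,
    PulseModelParams,
    analytic_derivative,
    default_age_effect_map,
    elderly_preset,
    generate_cohort,
    generate_pulse,
    generate_recording,
    synthesize_features,
)
from ppgage.simulate import read_recording, write_recording


def single_gaussian(center=0.25, width=0.08, duration=0.8):
    return PulseModelParams(
        duration=duration,
        amplitudes=(1.0, 0.0, 0.0),
        centers=(center, 0.5, 0.75),
        widths=(width, 0.1, 0.1),
    )


class TestGeneratePulse:
    def test_zero_amplitudes_give_flat_zero(self):
        p = PulseModelParams(0.8, (0.0, 0.0, 0.0), (0.2, 0.5, 0.7), (0.05, 0.05, 0.05))
        assert np.all(generate_pulse(p, 250.0) == 0.0)

    def test_single_gaussian_argmax_at_sample_50(self):
        w = generate_pulse(single_gaussian(), 250.0)
        assert int(np.argmax(w)) == round(0.25 * 0.8 * 250)  # = 50

    def test_preset_has_one_dicrotic_minimum_after_systolic_peak(self, preset_pulse):
        _, w = preset_pulse
        peak = int(np.argmax(w))
        minima = [
            i for i in range(peak + 1, len(w) - 1) if w[i - 1] > w[i] <= w[i + 1]
        ]
        assert len(minima) == 1

    def test_invalid_centers_rejected(self):
        with pytest.raises(ParameterError):
            PulseModelParams(0.8, (1, 0.3, 0.2), (0.5, 0.2, 0.7), (0.05, 0.05, 0.05))

    def test_low_fs_rejected(self):
        with pytest.raises(ParameterError):
            generate_pulse(single_gaussian(), 50.0)


class TestAnalyticDerivative:
    def test_zero_amplitudes_any_order(self):
        p = PulseModelParams(0.8, (0.0, 0.0, 0.0), (0.2, 0.5, 0.7), (0.05, 0.05, 0.05))
        for order in (1, 2, 3):
            assert np.all(analytic_derivative(p, order, 250.0) == 0.0)

    def test_first_derivative_crosses_zero_at_center(self):
        d1 = analytic_derivative(single_gaussian(), 1, 250.0)
        assert d1[49] > 0 > d1[51]

    def test_unsupported_order(self):
        with pytest.raises(ParameterError):
            analytic_derivative(single_gaussian(), 4, 250.0)

    def test_second_difference_converges_to_analytic(self):
        fs = 2000.0
        p = elderly_preset()
        w = generate_pulse(p, fs)
        d2 = analytic_derivative(p, 2, fs)
        num = np.gradient(np.gradient(w, 1 / fs), 1 / fs)
        interior = slice(5, -5)
        dev = np.max(np.abs(num[interior] - d2[interior]))
        assert dev < 1e-3 * np.max(np.abs(d2))

    def test_numerical_error_decreases_with_fs(self):
        p = elderly_preset()
        errs = []
        for fs in (250.0, 1000.0, 4000.0):
            w = generate_pulse(p, fs)
            d2 = analytic_derivative(p, 2, fs)
            num = np.gradient(np.gradient(w, 1 / fs), 1 / fs)
            errs.append(np.max(np.abs(num[5:-5] - d2[5:-5])) / np.max(np.abs(d2)))
        assert errs[0] > errs[1] > errs[2]


class TestGenerateRecording:
    def test_clean_recording_is_exact_tiling(self, clean_recording):
        on = clean_recording.onsets
        period = np.unique(np.diff(on))
        assert period.size == 1  # all beats the same length
        assert np.all(on == on[0] + period[0] * np.arange(on.size))

    def test_determinism(self, clean_spec):
        a = generate_recording(clean_spec, 70.0, seed=11)
        b = generate_recording(clean_spec, 70.0, seed=11)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.onsets, b.onsets)

    def test_beat_count_near_expected(self):
        spec = CohortSpec(recording_duration=300, heart_rate_sd=0, seed=4)
        rec = generate_recording(spec, 72.5, seed=4)  # HR exactly 70 bpm
        assert abs(len(rec.onsets) - 350) <= 2

    def test_length_equals_duration_times_fs(self, clean_recording, clean_spec):
        assert len(clean_recording.samples) == round(
            clean_spec.recording_duration * clean_spec.fs
        )


class TestGenerateCohort:
    def test_single_subject(self):
        recs, ages = generate_cohort(CohortSpec(n_subjects=1, recording_duration=20))
        assert len(recs) == 1 and len(ages) == 1

    def test_master_seed_determinism(self):
        spec = CohortSpec(n_subjects=3, recording_duration=20, seed=7)
        recs_a, ages_a = generate_cohort(spec)
        recs_b, ages_b = generate_cohort(spec)
        assert ages_a.equals(ages_b)
        for a, b in zip(recs_a, recs_b):
            assert np.array_equal(a.samples, b.samples)

    def test_ages_within_range(self, small_cohort):
        _, ages = small_cohort
        assert ages["age"].between(60, 85).all()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ParameterError):
            CohortSpec(n_subjects=0)
        with pytest.raises(ParameterError):
            CohortSpec(fs=15.0)
        with pytest.raises(ParameterError):
            CohortSpec(age_range=(85.0, 60.0))


class TestAgeEffectMap:
    def test_monotone_ground_truth_encoding(self):
        ages = np.linspace(60, 85, 6)
        params = [default_age_effect_map(a, 0.857) for a in ages]
        refl = [p.amplitudes[1] for p in params]
        dic = [p.amplitudes[2] for p in params]
        assert all(x < y for x, y in zip(refl, refl[1:]))  # reflection rises
        assert all(x > y for x, y in zip(dic, dic[1:]))  # dicrotic falls


class TestSynthesizeFeatures:
    def test_exact_linear_map_when_noiseless(self):
        df = synthesize_features(50, seed=2, noise_sd=0.0)
        expected = 109.65 + 22.16 * df["AI"] - 0.05 * df["sum_tdppg_e4"]
        assert np.allclose(df["age"], expected)

    def test_ai_consistent_with_components(self):
        df = synthesize_features(50, seed=2)
        assert np.allclose(df["AI"], df["b_a"] - df["c_a"] - df["d_a"] - df["e_a"])

    def test_determinism(self):
        assert synthesize_features(30, seed=5).equals(synthesize_features(30, seed=5))


class TestRecordingIO:
    def test_round_trip(self, tmp_path, clean_recording):
        write_recording(clean_recording, tmp_path / "rec")
        back = read_recording(tmp_path / "rec")
        assert back.fs == clean_recording.fs
        assert back.subject_age == clean_recording.subject_age
        assert np.allclose(back.samples, clean_recording.samples, atol=1e-6)
        assert np.array_equal(back.onsets, clean_recording.onsets)
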