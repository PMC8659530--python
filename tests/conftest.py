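import numpy as np
import pytest

from ppgage import (
    CohortSpec,
    elderly_preset,
    extract_cohort_features,
    generate_cohort,
    generate_pulse,
    generate_recording,
    preprocess,
)
from ppgage.preprocess import FilteredSignal


@pytest.fixture(scope="session")
def clean_spec():
    """Noiseless, jitter-free study design: exact tiling of identical pulses."""
    return CohortSpec(
        recording_duration=30,
        heart_rate_sd=0,
        beat_jitter_sd=0,
        amp_jitter_sd=0,
        morph_jitter_sd=0,
        respiratory_drift_amp=0,
        trend_amp=0,
        noise_sd=0,
        seed=1,
    )


@pytest.fixture(scope="session")
def clean_recording(clean_spec):
    return generate_recording(clean_spec, 72.5, seed=1)


@pytest.fixture(scope="session")
def clean_raw(clean_recording):
    """The clean tiling wrapped as a FilteredSignal without any filtering."""
    return FilteredSignal(samples=clean_recording.samples, fs=clean_recording.fs)


@pytest.fixture(scope="session")
def clean_filtered(clean_recording):
    return preprocess(clean_recording)


@pytest.fixture(scope="session")
def preset_pulse():
    params = elderly_preset()
    return params, generate_pulse(params, 250.0)


@pytest.fixture(scope="session")
def small_cohort():
    spec = CohortSpec(n_subjects=10, recording_duration=60, seed=3)
    recordings, ages = generate_cohort(spec)
    return recordings, ages


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    recordings, _ = small_cohort
    return extract_cohort_features(recordings)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
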