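"""Synthetic earlobe-PPG cohort generator.

Real elderly-cohort recordings are not publicly distributable, so the rest of
the pipeline is developed and validated against simulated recordings with a
fully known ground truth.  Each cardiac beat is modelled as a sum of three
Gaussian components -- systolic upstroke, reflection wave and dicrotic
(diastolic) wave.  The mixture is smooth and analytically differentiable to
any order, which gives an exact oracle for the numerical second- and
third-derivative stages (SDPPG / TDPPG).

A recording is a concatenation of beats with per-beat duration jitter
(log-normal), per-beat gain jitter, a sinusoidal respiratory baseline, a slow
linear trend and additive white noise.  Ages map monotonically onto pulse
morphology (``default_age_effect_map``), so downstream features carry a known
age signal: with increasing age the systolic component broadens, the
reflection wave grows and arrives earlier, and the dicrotic wave shrinks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

__all__ = [
    "PulseModelParams",
    "CohortSpec",
    "PPGRecording",
    "default_age_effect_map",
    "elderly_preset",
    "generate_pulse",
    "analytic_derivative",
    "generate_recording",
    "generate_cohort",
    "synthesize_features",
    "write_recording",
    "read_recording",
]


@dataclass(frozen=True)
class PulseModelParams:
    """Three-Gaussian surrogate of one PPG beat.

    ``centers`` and ``widths`` are fractions of ``duration`` so the same
    morphology can be re-sampled at any beat length.  Component order is
    (systolic, reflection, dicrotic); the systolic gain must be the largest.
    """

    duration: float  # seconds
    amplitudes: tuple[float, float, float]
    centers: tuple[float, float, float]
    widths: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ParameterError(f"pulse duration must be > 0, got {self.duration}")
        for name in ("amplitudes", "centers", "widths"):
            vals = getattr(self, name)
            if len(vals) != 3:
                raise ParameterError(f"{name} must have exactly 3 entries")
        c = self.centers
        if not (0.0 < c[0] < c[1] < c[2] < 1.0):
            raise ParameterError(f"centers must be strictly increasing in (0,1), got {c}")
        if min(self.widths) <= 0:
            raise ParameterError(f"widths must be > 0, got {self.widths}")
        a = self.amplitudes
        if a[0] < max(a[1], a[2]):
            raise ParameterError("systolic amplitude must be the largest component gain")

    def absolute_components(self):
        """Yield (amplitude, center_s, width_s) triples in absolute seconds."""
        for A, c, w in zip(self.amplitudes, self.centers, self.widths):
            yield A, c * self.duration, w * self.duration


def default_age_effect_map(age: float, duration: float = 60.0 / 70.0) -> PulseModelParams:
    """Monotone age -> morphology mapping.

    With increasing age the reflection wave gains amplitude and the dicrotic
    wave loses amplitude.  The reflection component is centred sqrt(3)
    reflection-widths after the systolic centre, which places its positive
    curvature lobe on the b-wave and its curvature trough just after the
    c-wave: a growing reflection therefore raises b/a, depresses c/a and the
    d-wave, and raises the Aging Index, encoding the age directions the
    feature set is meant to detect (c/a and the third-derivative sum fall
    with age; b/a, T_ac and AI rise).
    """
    u = float(np.clip((age - 72.5) / 12.5, -1.6, 1.6))
    w_refl = 0.075
    amp_refl = 0.35 + 0.15 * u
    amp_dic = max(0.04, 0.22 - 0.08 * u)
    return PulseModelParams(
        duration=duration,
        amplitudes=(1.0, amp_refl, amp_dic),
        centers=(0.17, 0.17 + np.sqrt(3.0) * w_refl, 0.58),
        widths=(0.055, w_refl, 0.075),
    )


def elderly_preset(duration: float = 60.0 / 70.0) -> PulseModelParams:
    """Default morphology of a 72.5-year-old subject."""
    return default_age_effect_map(72.5, duration)


@dataclass
class CohortSpec:
    """Study-design parameters for a simulated cohort.

    Defaults emulate the target population: ~84 elderly subjects, ages
    centred near 71 years, 5-minute earlobe recordings sampled at 250 Hz,
    resting heart rate around 70 bpm with mild beat-to-beat variability,
    respiratory baseline at ~0.25 Hz and a small broadband noise floor.
    """

    n_subjects: int = 84
    age_range: tuple[float, float] = (60.0, 85.0)
    age_mean: float = 71.19
    age_sd: float = 6.97
    age_distribution: str = "truncnorm"  # or "uniform"
    recording_duration: float = 300.0  # seconds
    fs: float = 250.0  # Hz
    heart_rate_mean: float = 70.0  # bpm, at the cohort mean age
    heart_rate_sd: float = 2.0  # bpm, between subjects
    heart_rate_age_slope: float = 0.35  # bpm decline per year of age
    beat_jitter_sd: float = 0.03  # log-normal sigma of per-beat duration
    amp_jitter_sd: float = 0.05  # per-beat gain s.d.
    morph_jitter_sd: float = 0.06  # per-subject log-normal sigma on morphology
    respiratory_drift_freq: float = 0.25  # Hz
    respiratory_drift_amp: float = 0.10  # fraction of pulse amplitude
    trend_amp: float = 0.20  # total linear drift over the recording
    noise_sd: float = 0.02  # fraction of pulse amplitude
    age_effect_map: Callable[[float, float], PulseModelParams] = default_age_effect_map
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        lo, hi = self.age_range
        if not (0.0 < lo < hi < 120.0):
            raise ParameterError(f"age_range must lie within (0, 120), got {self.age_range}")
        # the analysis band-pass tops out at 9 Hz; Nyquist must clear it
        if self.fs <= 2 * 9.0:
            raise ParameterError(f"fs={self.fs} must exceed twice the 9 Hz analysis band")
        if self.recording_duration <= 0:
            raise ParameterError("recording_duration must be > 0")
        if self.age_distribution not in ("truncnorm", "uniform"):
            raise ParameterError(f"unknown age_distribution {self.age_distribution!r}")


@dataclass
class PPGRecording:
    """A single-channel PPG sample stream plus its simulation ground truth."""

    samples: np.ndarray
    fs: float
    subject_age: float
    subject_id: str = "s000"
    onsets: np.ndarray | None = None  # ground-truth beat start indices
    beat_params: list[PulseModelParams] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


def generate_pulse(params: PulseModelParams, fs: float) -> np.ndarray:
    """Sample one beat of the Gaussian-mixture pulse at ``fs`` Hz."""
    if fs < 100:
        raise ParameterError(f"fs must be >= 100 Hz, got {fs}")
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs
    y = np.zeros(n)
    for A, mu, s in params.absolute_components():
        if A != 0.0:
            y += A * np.exp(-0.5 * ((t - mu) / s) ** 2)
    return y


def analytic_derivative(params: PulseModelParams, order: int, fs: float) -> np.ndarray:
    """Closed-form time derivative of the Gaussian-mixture pulse.

    For a Gaussian g(t) = exp(-z^2/2) with z = (t-mu)/s the derivatives are
    Hermite-polynomial multiples of g: g' = -(z/s) g, g'' = (z^2-1)/s^2 g,
    g''' = -(z^3-3z)/s^3 g.  Serves as the oracle for numerical SDPPG/TDPPG.
    """
    if order not in (1, 2, 3):
        raise ParameterError(f"derivative order must be 1, 2 or 3, got {order}")
    if fs < 100:
        raise ParameterError(f"fs must be >= 100 Hz, got {fs}")
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs
    y = np.zeros(n)
    for A, mu, s in params.absolute_components():
        if A == 0.0:
            continue
        z = (t - mu) / s
        g = np.exp(-0.5 * z * z)
        if order == 1:
            y += A * (-z / s) * g
        elif order == 2:
            y += A * ((z * z - 1.0) / s**2) * g
        else:
            y += A * (-(z**3 - 3.0 * z) / s**3) * g
    return y


def _subject_morphology(
    base: PulseModelParams, rng: np.random.Generator, sigma: float
) -> PulseModelParams:
    """Perturb a subject's morphology around the age-mapped base shape."""
    if sigma <= 0:
        return base
    amp = list(base.amplitudes)
    wid = list(base.widths)
    ctr = list(base.centers)
    for i in (1, 2):
        amp[i] = float(amp[i] * rng.lognormal(0.0, sigma))
    for i in range(3):
        wid[i] = float(wid[i] * rng.lognormal(0.0, sigma))
    ctr[1] = float(np.clip(ctr[1] + rng.normal(0.0, 0.3 * sigma), ctr[0] + 0.05, ctr[2] - 0.05))
    amp[1] = min(amp[1], 0.95 * amp[0])
    amp[2] = min(amp[2], 0.95 * amp[0])
    return PulseModelParams(base.duration, tuple(amp), tuple(ctr), tuple(wid))


def generate_recording(
    spec: CohortSpec,
    subject_age: float,
    seed: int | None = None,
    subject_id: str = "s000",
) -> PPGRecording:
    """Simulate one subject's recording with stored ground truth.

    Beats are generated on disjoint segments (no cross-beat overlap), so the
    stored onset of beat *k* is exactly the first sample of its segment.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_total = int(round(spec.recording_duration * spec.fs))

    # resting heart rate declines mildly with age, lengthening the pulse
    hr_center = spec.heart_rate_mean - spec.heart_rate_age_slope * (subject_age - 72.5)
    hr = float(np.clip(rng.normal(hr_center, spec.heart_rate_sd), 40.0, 120.0))
    mean_beat = 60.0 / hr
    base = spec.age_effect_map(subject_age, mean_beat)
    morph = _subject_morphology(base, rng, spec.morph_jitter_sd)

    # Morphology timing is fixed in absolute time for a subject (systolic and
    # reflection timing do not track beat length physiologically); per-beat
    # duration jitter only stretches or truncates the diastolic tail.
    shape_len = int(round(1.25 * mean_beat * spec.fs))
    t_shape = np.arange(shape_len) / spec.fs
    shape = np.zeros(shape_len)
    for A, mu, s in morph.absolute_components():
        if A != 0.0:
            shape += A * np.exp(-0.5 * ((t_shape - mu) / s) ** 2)

    samples = np.zeros(n_total)
    onsets: list[int] = []
    beat_params: list[PulseModelParams] = []
    pos = 0
    while pos < n_total:
        if spec.beat_jitter_sd > 0:
            dur = float(np.clip(mean_beat * rng.lognormal(0.0, spec.beat_jitter_sd), 0.3, 2.0))
        else:
            dur = mean_beat
        n_beat = int(round(dur * spec.fs))
        beat = shape[:n_beat] if n_beat <= shape_len else np.pad(shape, (0, n_beat - shape_len))
        if spec.amp_jitter_sd > 0:
            beat = beat * max(0.2, 1.0 + rng.normal(0.0, spec.amp_jitter_sd))
        end = min(pos + n_beat, n_total)
        samples[pos:end] = beat[: end - pos]
        if end - pos == n_beat:  # only complete beats enter the ground truth
            onsets.append(pos)
            beat_params.append(morph)
        pos += n_beat

    t = np.arange(n_total) / spec.fs
    if spec.respiratory_drift_amp > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        samples += spec.respiratory_drift_amp * np.sin(
            2.0 * np.pi * spec.respiratory_drift_freq * t + phase
        )
    if spec.trend_amp != 0:
        samples += spec.trend_amp * (t / spec.recording_duration - 0.5)
    if spec.noise_sd > 0:
        samples += rng.normal(0.0, spec.noise_sd, n_total)

    return PPGRecording(
        samples=samples,
        fs=spec.fs,
        subject_age=float(subject_age),
        subject_id=subject_id,
        onsets=np.asarray(onsets, dtype=int),
        beat_params=beat_params,
        meta={"seed": seed, "heart_rate_bpm": hr},
    )


def _draw_ages(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.age_range
    if spec.age_distribution == "uniform":
        return rng.uniform(lo, hi, spec.n_subjects)
    a = (lo - spec.age_mean) / spec.age_sd
    b = (hi - spec.age_mean) / spec.age_sd
    return stats.truncnorm.rvs(
        a, b, loc=spec.age_mean, scale=spec.age_sd, size=spec.n_subjects, random_state=rng
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[PPGRecording], pd.DataFrame]:
    """Generate a full cohort; per-subject seeds derive from the master seed."""
    rng = np.random.default_rng(spec.seed)
    ages = _draw_ages(spec, rng)
    sub_seeds = rng.integers(0, 2**31 - 1, size=spec.n_subjects)
    recordings = []
    for i, (age, s) in enumerate(zip(ages, sub_seeds)):
        sid = f"s{i:03d}"
        recordings.append(generate_recording(spec, float(age), int(s), subject_id=sid))
    table = pd.DataFrame(
        {"subject_id": [r.subject_id for r in recordings], "age": np.round(ages, 2)}
    )
    return recordings, table


# ---------------------------------------------------------------------------
# feature-level synthesis (for exercising the regression / network stages
# without running the waveform pipeline)

_FEATURE_MOMENTS = {
    # plausible elderly-cohort feature means and spreads
    "b_a": (-1.10, 0.07),
    "c_a": (0.14, 0.06),
    "d_a": (0.03, 0.06),
    "e_a": (0.21, 0.05),
    "T_ab_ms": (44.21, 2.57),
    "T_ac_ms": (88.21, 6.48),
    "T_ad_ms": (108.07, 5.03),
    "T_ae_ms": (128.0, 6.0),
    "sum_tdppg_e4": (100.18, 10.0),
}


def synthesize_features(
    n: int,
    seed: int,
    intercept: float = 109.65,
    coefficients: dict[str, float] | None = None,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Draw independent feature vectors and ages from a known linear model.

    The Aging Index is derived from the sampled ratios (AI = b/a - c/a - d/a
    - e/a) so its spread is consistent with them.  Ages follow
    ``intercept + sum(coef * feature) + N(0, noise_sd)``; with the default
    coefficients only AI and the third-derivative sum carry age signal while
    every other feature is an independent decoy.
    """
    if coefficients is None:
        coefficients = {"AI": 22.16, "sum_tdppg_e4": -0.05}
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {k: rng.normal(m, s, n) for k, (m, s) in _FEATURE_MOMENTS.items()}
    )
    df["AI"] = df["b_a"] - df["c_a"] - df["d_a"] - df["e_a"]
    age = np.full(n, float(intercept))
    for name, coef in coefficients.items():
        age = age + coef * df[name].to_numpy()
    age = age + rng.normal(0.0, noise_sd, n)
    df.insert(0, "age", age)
    df.insert(0, "subject_id", [f"s{i:03d}" for i in range(n)])
    return df


# ---------------------------------------------------------------------------
# plain-text I/O: two-column CSV + JSON sidecar

def write_recording(rec: PPGRecording, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.csv`` (time_s, amplitude) and ``<prefix>.json`` sidecar."""
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    pd.DataFrame({"time_s": rec.time, "amplitude": rec.samples}).to_csv(
        csv_path, index=False, float_format="%.6f"
    )
    sidecar = {
        "fs": rec.fs,
        "subject_id": rec.subject_id,
        "age": rec.subject_age,
        "seed": rec.meta.get("seed"),
        "ground_truth": None,
    }
    if rec.onsets is not None:
        sidecar["ground_truth"] = {
            "onsets": [int(i) for i in rec.onsets],
            "beat_params": [dataclasses.asdict(p) for p in (rec.beat_params or [])],
        }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, json_path


def read_recording(prefix: str | Path) -> PPGRecording:
    """Read a recording written by :func:`write_recording`."""
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".csv"))
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    onsets = None
    beat_params = None
    gt = sidecar.get("ground_truth")
    if gt:
        onsets = np.asarray(gt["onsets"], dtype=int)
        beat_params = [
            PulseModelParams(
                p["duration"], tuple(p["amplitudes"]), tuple(p["centers"]), tuple(p["widths"])
            )
            for p in gt.get("beat_params", [])
        ]
    return PPGRecording(
        samples=df["amplitude"].to_numpy(),
        fs=float(sidecar["fs"]),
        subject_age=float(sidecar["age"]),
        subject_id=str(sidecar["subject_id"]),
        onsets=onsets,
        beat_params=beat_params,
        meta={"seed": sidecar.get("seed")},
    )
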