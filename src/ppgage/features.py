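"""Per-subject pulse-wave features: amplitude ratios, wave intervals,
Aging Index and the third-derivative energy statistic.

Ten features are computed per subject from the SDPPG fiducials of the
representative pulse: the amplitude ratios b/a, c/a, d/a, e/a; the intervals
T_ab, T_ac, T_ad, T_ae (ms from the a-wave); the Aging Index
AI = (b - c - d - e)/a; and the sum over beats of the RMS third-derivative
amplitude, reported on a x10^4 scale (``sum_tdppg_e4``).

For the third-derivative sum each retained beat is normalized to unit
peak-to-peak before differentiation, so the statistic is independent of the
device gain; the derivative is taken in per-sample units, which puts the
x10^4-scaled sum of a 5-minute resting recording near 10^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegeneratePulseError, ParameterError, PipelineError, PPGAgeError
from .fiducials import (
    SG_POLYORDER_DEFAULT,
    SG_WINDOW_MS_DEFAULT,
    FiducialSet,
    compute_derivatives,
    detect_fiducials,
    differentiate,
)
from .preprocess import FilterSpec, preprocess
from .segment import (
    MIN_BEATS_DEFAULT,
    detect_pulse_boundaries,
    extract_beats,
    representative_pulse,
    select_beats,
)
from .simulate import PPGRecording

__all__ = [
    "FeatureVector",
    "FEATURE_COLUMNS",
    "amplitude_ratios",
    "time_intervals",
    "aging_index",
    "sum_tdppg",
    "extract_features",
    "extract_cohort_features",
]

log = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "b_a", "c_a", "d_a", "e_a",
    "T_ab_ms", "T_ac_ms", "T_ad_ms", "T_ae_ms",
    "AI", "sum_tdppg_e4",
]


@dataclass(frozen=True)
class FeatureVector:
    b_a: float
    c_a: float
    d_a: float
    e_a: float
    T_ab_ms: float
    T_ac_ms: float
    T_ad_ms: float
    T_ae_ms: float
    AI: float
    sum_tdppg_e4: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in FEATURE_COLUMNS}


def amplitude_ratios(fid: FiducialSet) -> tuple[float, float, float, float]:
    """(b/a, c/a, d/a, e/a); the a-wave amplitude must be nonzero."""
    if fid.a == 0:
        raise DegeneratePulseError("a-wave amplitude is zero; ratios undefined")
    return (fid.b / fid.a, fid.c / fid.a, fid.d / fid.a, fid.e / fid.a)


def time_intervals(fid: FiducialSet) -> tuple[float, float, float, float]:
    """(T_ab, T_ac, T_ad, T_ae) in milliseconds from the a-wave."""
    return (
        fid.t_b - fid.t_a,
        fid.t_c - fid.t_a,
        fid.t_d - fid.t_a,
        fid.t_e - fid.t_a,
    )


def aging_index(fid: FiducialSet) -> float:
    """Aging Index AI = (b - c - d - e) / a."""
    if fid.a == 0:
        raise DegeneratePulseError("a-wave amplitude is zero; AI undefined")
    return (fid.b - fid.c - fid.d - fid.e) / fid.a


def sum_tdppg(
    beats: list[np.ndarray],
    fs: float,
    normalize: bool = True,
    per_sample: bool = True,
    per_minute: bool = False,
    window_ms: float = SG_WINDOW_MS_DEFAULT,
    polyorder: int = SG_POLYORDER_DEFAULT,
    duration_s: float | None = None,
) -> float:
    """Sum over beats of the RMS third-derivative amplitude, x10^4.

    Each beat is normalized to unit peak-to-peak (device-gain independence)
    unless ``normalize=False``; ``per_minute=True`` divides by the recording
    duration in minutes so the statistic no longer grows with recording
    length (off by default).
    """
    if not beats:
        raise ParameterError("sum_tdppg needs at least one beat")
    total = 0.0
    for beat in beats:
        b = np.asarray(beat, dtype=float)
        if normalize:
            ptp = float(np.ptp(b))
            if ptp > 0:
                b = b / ptp
        td = differentiate(b, fs, 3, window_ms, polyorder, per_sample=per_sample)
        total += float(np.sqrt(np.mean(td**2)))
    if per_minute:
        if duration_s is None:
            raise ParameterError("per_minute normalization needs duration_s")
        total /= duration_s / 60.0
    return total * 1e4


@dataclass
class FeatureConfig:
    """Knobs of the waveform-to-features pipeline (defaults follow the
    published protocol where it states values)."""

    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    min_beats: int = MIN_BEATS_DEFAULT
    interval_window_ms: tuple[float, float] = (300.0, 2000.0)
    length_tolerance: float = 0.25
    amplitude_mad_limit: float = 3.0
    sg_window_ms: float = SG_WINDOW_MS_DEFAULT
    sg_polyorder: int = SG_POLYORDER_DEFAULT
    a_search_frac: float = 0.3
    tdppg_normalize: bool = True
    tdppg_per_sample: bool = True
    tdppg_per_minute: bool = False
    tdppg_source: str = "beats"  # or "representative"


def extract_features(
    recording: PPGRecording, config: FeatureConfig | None = None
) -> FeatureVector:
    """Full pipeline for one subject: preprocess -> segment -> representative
    pulse -> derivatives -> fiducials -> features.

    Errors from any stage are re-raised as :class:`PipelineError` carrying the
    stage name.
    """
    cfg = config or FeatureConfig()
    stage = "preprocess"
    try:
        filtered = preprocess(recording, cfg.filter_spec)
        stage = "segmentation"
        boundaries = detect_pulse_boundaries(
            filtered, min_beats=cfg.min_beats, interval_window_ms=cfg.interval_window_ms
        )
        beats = select_beats(
            extract_beats(filtered, boundaries), cfg.length_tolerance, cfg.amplitude_mad_limit
        )
        rep = representative_pulse(
            filtered, boundaries, cfg.min_beats, cfg.length_tolerance, cfg.amplitude_mad_limit
        )
        stage = "derivatives"
        deriv = compute_derivatives(rep, cfg.sg_window_ms, cfg.sg_polyorder)
        stage = "fiducials"
        fid = detect_fiducials(
            deriv.sdppg, rep.fs, cfg.a_search_frac,
            window_ms=cfg.sg_window_ms, polyorder=cfg.sg_polyorder,
        )
        stage = "features"
        b_a, c_a, d_a, e_a = amplitude_ratios(fid)
        t_ab, t_ac, t_ad, t_ae = time_intervals(fid)
        ai = aging_index(fid)
        tdppg_beats = [rep.samples] if cfg.tdppg_source == "representative" else beats
        s_td = sum_tdppg(
            tdppg_beats,
            rep.fs,
            normalize=cfg.tdppg_normalize,
            per_sample=cfg.tdppg_per_sample,
            per_minute=cfg.tdppg_per_minute,
            window_ms=cfg.sg_window_ms,
            polyorder=cfg.sg_polyorder,
            duration_s=recording.duration,
        )
    except PPGAgeError as err:
        raise PipelineError(stage, str(err)) from err
    return FeatureVector(b_a, c_a, d_a, e_a, t_ab, t_ac, t_ad, t_ae, ai, s_td)


def extract_cohort_features(
    recordings: list[PPGRecording], config: FeatureConfig | None = None
) -> pd.DataFrame:
    """Feature table with one row per subject; failures are logged and skipped.

    Columns: subject_id, age, then :data:`FEATURE_COLUMNS`.
    """
    rows = []
    for rec in recordings:
        try:
            fv = extract_features(rec, config)
        except PipelineError as err:
            log.warning("subject %s skipped: %s", rec.subject_id, err)
            continue
        rows.append({"subject_id": rec.subject_id, "age": rec.subject_age, **fv.as_dict()})
    return pd.DataFrame(rows, columns=["subject_id", "age", *FEATURE_COLUMNS])
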