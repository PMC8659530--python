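"""Pulse segmentation and representative-pulse averaging.

A beat ends at the deepest point of the waveform after the dicrotic notch:
operationally, the global minimum of the filtered signal between successive
systolic peaks.  The next sample starts the following beat, and consecutive
onsets define the pulse-to-pulse interval.  The representative pulse is the
sample-wise average of onset-aligned beats, after excluding beats with an
implausible interval, an outlying length or an outlying amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ParameterError, SegmentationError
from .preprocess import FilteredSignal

__all__ = [
    "PulseBoundaries",
    "RepresentativePulse",
    "detect_pulse_boundaries",
    "extract_beats",
    "representative_pulse",
]

MIN_BEATS_DEFAULT = 10


@dataclass
class PulseBoundaries:
    """0-based beat onset indices; beat k spans [onset_k, onset_{k+1})."""

    onset_indices: np.ndarray
    fs: float
    interval_window_ms: tuple[float, float] = (300.0, 2000.0)

    @property
    def intervals_ms(self) -> np.ndarray:
        return np.diff(self.onset_indices) / self.fs * 1000.0

    @property
    def valid_beat_mask(self) -> np.ndarray:
        """True where the pulse-to-pulse interval is physiologically plausible."""
        iv = self.intervals_ms
        lo, hi = self.interval_window_ms
        return (iv >= lo) & (iv <= hi)


@dataclass
class RepresentativePulse:
    samples: np.ndarray
    fs: float
    n_beats_used: int
    beat_length_policy: str = "truncate-to-min"


def detect_pulse_boundaries(
    filtered: FilteredSignal,
    min_beats: int = MIN_BEATS_DEFAULT,
    min_peak_separation_s: float = 0.3,
    prominence_frac: float = 0.3,
    interval_window_ms: tuple[float, float] = (300.0, 2000.0),
) -> PulseBoundaries:
    """Locate beat onsets from systolic peaks and inter-peak minima."""
    x = np.asarray(filtered.samples, dtype=float)
    fs = filtered.fs
    if x.size < 2 * fs:
        raise SegmentationError(f"need >= 2 s of signal, got {x.size / fs:.2f} s")
    scale = float(np.percentile(x, 95) - np.percentile(x, 5))
    if scale <= 0 or not np.isfinite(scale):
        raise SegmentationError("flat or non-finite signal: no pulses detectable")
    peaks, _ = signal.find_peaks(
        x,
        distance=max(1, int(round(min_peak_separation_s * fs))),
        prominence=prominence_frac * scale,
    )
    if peaks.size < min_beats + 1:
        raise SegmentationError(
            f"only {peaks.size} systolic peaks found "
            f"(need {min_beats + 1}); signal scale {scale:.3g}"
        )
    onsets = np.empty(peaks.size - 1, dtype=int)
    for k in range(peaks.size - 1):
        seg = x[peaks[k] : peaks[k + 1]]
        onsets[k] = peaks[k] + int(np.argmin(seg)) + 1  # pulse end + 1 = next onset
    return PulseBoundaries(onsets, fs, interval_window_ms)


def extract_beats(
    filtered: FilteredSignal, boundaries: PulseBoundaries
) -> list[np.ndarray]:
    """Beat waveforms for every interval-plausible beat, onset-aligned."""
    x = np.asarray(filtered.samples, dtype=float)
    mask = boundaries.valid_beat_mask
    on = boundaries.onset_indices
    return [x[on[k] : on[k + 1]] for k in range(len(on) - 1) if mask[k]]


def _length_keep_mask(lengths, tolerance: float) -> np.ndarray:
    lengths = np.asarray(lengths, dtype=float)
    med = float(np.median(lengths))
    return np.abs(lengths - med) <= tolerance * med


def _amplitude_keep_mask(ptps, mad_limit: float) -> np.ndarray:
    ptp = np.asarray(ptps, dtype=float)
    med = float(np.median(ptp))
    mad = float(np.median(np.abs(ptp - med)))
    if mad <= 0:
        return np.ones(ptp.size, dtype=bool)
    return np.abs(ptp - med) <= mad_limit * 1.4826 * mad


def select_beats(
    beats: list[np.ndarray],
    length_tolerance: float = 0.25,
    amplitude_mad_limit: float = 3.0,
) -> list[np.ndarray]:
    """Drop beats whose length or peak-to-peak amplitude is an outlier.

    Lengths outside median +- ``length_tolerance`` are excluded; amplitudes
    further than ``amplitude_mad_limit`` robust standard deviations
    (1.4826 x MAD) from the median peak-to-peak are excluded.
    """
    if not beats:
        return []
    keep = _length_keep_mask([len(b) for b in beats], length_tolerance)
    beats = [b for b, k in zip(beats, keep) if k]
    if not beats:
        return []
    keep = _amplitude_keep_mask([float(np.ptp(b)) for b in beats], amplitude_mad_limit)
    return [b for b, k in zip(beats, keep) if k]


def representative_pulse(
    filtered: FilteredSignal,
    boundaries: PulseBoundaries,
    min_beats: int = MIN_BEATS_DEFAULT,
    length_tolerance: float = 0.25,
    amplitude_mad_limit: float = 3.0,
) -> RepresentativePulse:
    """Average onset-aligned beats sample-wise, truncated to the common length.

    The averaging grid is anchored on each beat's systolic peak with the
    onset-to-peak offset fixed at its within-recording median: the inter-beat
    minimum that defines the onset sits in a flat valley whose exact argmin
    jitters by many samples under noise, while the systolic peak is sharp.
    Anchoring on the peak keeps the beats aligned to within a sample without
    changing what counts as a beat (extents, intervals and exclusions still
    come from the onsets).  On noise-free recordings the two alignments
    coincide.
    """
    if min_beats < 1:
        raise ParameterError("min_beats must be >= 1")
    x = np.asarray(filtered.samples, dtype=float)
    mask = boundaries.valid_beat_mask
    on = boundaries.onset_indices
    pairs = [(int(on[k]), x[on[k] : on[k + 1]]) for k in range(len(on) - 1) if mask[k]]
    if pairs:
        keep = _length_keep_mask([len(b) for _, b in pairs], length_tolerance)
        pairs = [p for p, k in zip(pairs, keep) if k]
    if pairs:
        keep = _amplitude_keep_mask([float(np.ptp(b)) for _, b in pairs], amplitude_mad_limit)
        pairs = [p for p, k in zip(pairs, keep) if k]
    if len(pairs) < min_beats:
        raise SegmentationError(
            f"only {len(pairs)} beats survive exclusion (need {min_beats})"
        )
    n = min(len(b) for _, b in pairs)
    starts = [s for s, _ in pairs]
    peaks = [int(np.argmax(b)) for _, b in pairs]
    offset = int(np.median(peaks))
    windows = []
    for start, p in zip(starts, peaks):
        w0 = start + p - offset
        if 0 <= w0 and w0 + n <= x.size:
            windows.append(x[w0 : w0 + n])
    if len(windows) < min_beats:
        raise SegmentationError(
            f"only {len(windows)} alignable beats (need {min_beats})"
        )
    avg = np.mean(np.stack(windows), axis=0)
    return RepresentativePulse(samples=avg, fs=filtered.fs, n_beats_used=len(windows))
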