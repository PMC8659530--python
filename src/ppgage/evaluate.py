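"""Model assessment: Pearson correlation, MSE, error histogram and
Bland-Altman agreement between predicted and chronological age."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import ParameterError

__all__ = [
    "BlandAltman",
    "EvaluationReport",
    "pearson_r",
    "bland_altman",
    "error_histogram",
    "evaluate_predictions",
]


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("inputs must have equal length")
    if x.size < 3:
        raise ParameterError("need at least 3 points for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ParameterError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class BlandAltman:
    """Agreement between two measurements via their differences."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    inside_fraction: float


def bland_altman(predicted, actual) -> BlandAltman:
    """Differences predicted - actual with 95% limits of agreement
    (mean +- 1.96 SD) and the fraction of points inside the limits."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.size != a.size:
        raise ParameterError("predicted and actual must have equal length")
    if p.size < 3:
        raise ParameterError("need at least 3 pairs")
    d = p - a
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    inside = float(np.mean((d >= lo) & (d <= hi)))
    return BlandAltman(mean, sd, lo, hi, inside)


def error_histogram(errors, n_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of prediction errors with bins symmetric about zero.

    Returns (bin_edges, counts); counts always sum to the number of errors.
    """
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ParameterError("error_histogram needs at least one value")
    m = float(np.max(np.abs(e)))
    if m == 0.0:
        m = 0.5  # all-zero errors: a token symmetric range around 0
    edges = np.linspace(-m, m, n_bins + 1)
    counts, _ = np.histogram(e, bins=edges)
    # values exactly on the upper edge belong to the last bin (np convention),
    # so counts already conserve n
    return edges, counts


@dataclass
class EvaluationReport:
    r_per_split: dict = field(default_factory=dict)
    mse_per_split: dict = field(default_factory=dict)
    histogram_edges: list = field(default_factory=list)
    histogram_counts: list = field(default_factory=list)
    bland_altman: BlandAltman | None = None

    def to_json(self, path: str | Path) -> None:
        d = {
            "r_per_split": self.r_per_split,
            "mse_per_split": self.mse_per_split,
            "histogram_edges": list(self.histogram_edges),
            "histogram_counts": [int(c) for c in self.histogram_counts],
            "bland_altman": asdict(self.bland_altman) if self.bland_altman else None,
        }
        Path(path).write_text(json.dumps(d, indent=1, default=float))


def evaluate_predictions(
    predicted, actual, splits: dict[str, np.ndarray] | None = None, n_bins: int = 20
) -> EvaluationReport:
    """Assemble the full report; ``splits`` maps split name -> index array."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    groups = {"all": np.arange(p.size)}
    if splits:
        groups.update(splits)
    r = {k: pearson_r(p[idx], a[idx]) for k, idx in groups.items() if len(idx) >= 3}
    mse = {k: float(np.mean((p[idx] - a[idx]) ** 2)) for k, idx in groups.items()}
    edges, counts = error_histogram(p - a, n_bins)
    return EvaluationReport(
        r_per_split=r,
        mse_per_split=mse,
        histogram_edges=edges.tolist(),
        histogram_counts=counts.tolist(),
        bland_altman=bland_altman(p, a),
    )
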