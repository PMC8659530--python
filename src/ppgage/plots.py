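"""Optional figure output (PNG via the Agg backend, no display needed)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .evaluate import bland_altman, error_histogram  # noqa: E402

__all__ = [
    "plot_age_scatter",
    "plot_training_curve",
    "plot_error_histogram",
    "plot_bland_altman",
]


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_age_scatter(predicted, actual, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(actual, predicted, s=18, alpha=0.7)
    lo = min(np.min(actual), np.min(predicted))
    hi = max(np.max(actual), np.max(predicted))
    ax.plot([lo, hi], [lo, hi], "k--", lw=1, label="identity")
    ax.set_xlabel("chronological age (years)")
    ax.set_ylabel("predicted age (years)")
    ax.legend()
    return _save(fig, path)


def plot_training_curve(trace: dict, path: str | Path, best_epoch: int | None = None) -> Path:
    fig, ax = plt.subplots(figsize=(5.5, 4))
    for name in ("train", "validation", "test"):
        if name in trace:
            ax.semilogy(trace[name], label=name)
    if best_epoch is not None:
        ax.axvline(best_epoch, color="k", ls=":", lw=1, label=f"best epoch {best_epoch}")
    ax.set_xlabel("epoch")
    ax.set_ylabel("MSE (years$^2$)")
    ax.legend()
    return _save(fig, path)


def plot_error_histogram(errors, path: str | Path, n_bins: int = 20) -> Path:
    edges, counts = error_histogram(errors, n_bins)
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", edgecolor="k")
    ax.axvline(0.0, color="k", lw=1)
    ax.set_xlabel("prediction error (years)")
    ax.set_ylabel("count")
    return _save(fig, path)


def plot_bland_altman(predicted, actual, path: str | Path) -> Path:
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    ba = bland_altman(predicted, actual)
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.scatter((predicted + actual) / 2.0, predicted - actual, s=18, alpha=0.7)
    for y, style in ((ba.mean_diff, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, color="k", ls=style, lw=1)
    ax.set_xlabel("mean of predicted and actual age (years)")
    ax.set_ylabel("predicted − actual (years)")
    return _save(fig, path)
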