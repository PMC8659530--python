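"""Single-hidden-layer feed-forward network trained by Levenberg-Marquardt.

The age predictor is a shallow regressor: 4 inputs (c/a, T_ac, AI,
third-derivative sum), a tanh hidden layer (15 neurons by default) and a
linear output.  Inputs and target are min-max normalized to [-1, 1].

Training is full-batch damped Gauss-Newton on the squared-error Jacobian:
solve (J'J + mu*I) dw = J'r, accept the step when the training SSE drops
(mu /= 10), otherwise raise mu (*= 10) and retry.  One accepted step counts
as one epoch.  Training stops after ``patience`` consecutive epochs without
a new best validation MSE, and the weights from the best-validation epoch
are returned together with the full per-epoch MSE trace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, TrainingError
from .evaluate import pearson_r

__all__ = ["SplitSpec", "FFNNModel", "split_indices", "fit_ffnn", "hidden_layer_sweep"]

FFNN_INPUTS = ["c_a", "T_ac_ms", "AI", "sum_tdppg_e4"]


@dataclass(frozen=True)
class SplitSpec:
    """Random train/validation/test assignment (no stratification)."""

    train: float = 0.60
    validation: float = 0.20
    test: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train + self.validation + self.test - 1.0) > 1e-9:
            raise ParameterError("split fractions must sum to 1")
        if min(self.train, self.validation, self.test) <= 0:
            raise ParameterError("all split fractions must be positive")


def split_indices(n: int, split: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rng = np.random.default_rng(split.seed)
    perm = rng.permutation(n)
    n_test = int(round(split.test * n))
    n_val = int(round(split.validation * n))
    test = perm[:n_test]
    val = perm[n_test : n_test + n_val]
    train = perm[n_test + n_val :]
    return train, val, test


@dataclass
class FFNNModel:
    """Weights + normalization metadata + training trace."""

    input_names: list[str]
    W1: np.ndarray  # (n_hidden, n_inputs)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float
    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float
    y_max: float
    trace: dict = field(default_factory=dict)  # per-epoch MSE (original units)
    best_epoch: int = 0

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    def _norm_x(self, X: np.ndarray) -> np.ndarray:
        return 2.0 * (X - self.x_min) / (self.x_max - self.x_min) - 1.0

    def _denorm_y(self, y: np.ndarray) -> np.ndarray:
        return (y + 1.0) * (self.y_max - self.y_min) / 2.0 + self.y_min

    def predict(self, features) -> np.ndarray:
        """Predict ages; accepts a DataFrame (columns looked up by name) or
        an (n, 4) array in ``input_names`` order."""
        if isinstance(features, pd.DataFrame):
            X = features[self.input_names].to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(features, dtype=float))
        z = np.tanh(self._norm_x(X) @ self.W1.T + self.b1)
        return self._denorm_y(z @ self.w2 + self.b2)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "kind": "ffnn",
                    "input_names": self.input_names,
                    "W1": self.W1.tolist(),
                    "b1": self.b1.tolist(),
                    "w2": self.w2.tolist(),
                    "b2": self.b2,
                    "x_min": self.x_min.tolist(),
                    "x_max": self.x_max.tolist(),
                    "y_min": self.y_min,
                    "y_max": self.y_max,
                    "trace": self.trace,
                    "best_epoch": self.best_epoch,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FFNNModel":
        d = json.loads(Path(path).read_text())
        return cls(
            input_names=d["input_names"],
            W1=np.asarray(d["W1"]),
            b1=np.asarray(d["b1"]),
            w2=np.asarray(d["w2"]),
            b2=float(d["b2"]),
            x_min=np.asarray(d["x_min"]),
            x_max=np.asarray(d["x_max"]),
            y_min=float(d["y_min"]),
            y_max=float(d["y_max"]),
            trace=d.get("trace", {}),
            best_epoch=int(d.get("best_epoch", 0)),
        )


def _forward(Xn, W1, b1, w2, b2):
    z = np.tanh(Xn @ W1.T + b1)
    return z, z @ w2 + b2


def _pack(W1, b1, w2, b2):
    return np.concatenate([W1.ravel(), b1, w2, [b2]])


def _unpack(p, h, d):
    W1 = p[: h * d].reshape(h, d)
    b1 = p[h * d : h * d + h]
    w2 = p[h * d + h : h * d + 2 * h]
    b2 = p[-1]
    return W1, b1, w2, b2


def fit_ffnn(
    features,
    ages,
    n_hidden: int = 15,
    split: SplitSpec = SplitSpec(),
    seed: int = 0,
    max_epochs: int = 1000,
    patience: int = 6,
    mu_init: float = 1e-3,
    mu_max: float = 1e10,
    input_names: list[str] | None = None,
) -> FFNNModel:
    """Train the network; returns the best-validation-epoch weights.

    ``features`` is a DataFrame with the input columns or an (n, d) array.
    The per-epoch MSE trace (train/validation/test, original age units) is
    stored on the returned model, and ``best_epoch`` indexes the epoch whose
    validation MSE was lowest (0 = initial weights).
    """
    if isinstance(features, pd.DataFrame):
        names = input_names or [c for c in FFNN_INPUTS if c in features.columns]
        if input_names is None and len(names) != len(FFNN_INPUTS):
            names = [c for c in features.columns if c not in ("subject_id", "age")]
        X = features[names].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        names = input_names or [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(ages, dtype=float)
    n, d = X.shape
    if n != y.size:
        raise ParameterError("features and ages disagree in length")
    if n_hidden < 1:
        raise ParameterError("n_hidden must be >= 1")

    tr, va, te = split_indices(n, split)
    if min(len(tr), len(va), len(te)) < 1:
        raise ParameterError("each split must contain at least one sample")

    x_min, x_max = X[tr].min(axis=0), X[tr].max(axis=0)
    if np.any(x_max - x_min <= 0):
        flat = [names[i] for i in np.where(x_max - x_min <= 0)[0]]
        raise ParameterError(f"constant feature(s) on the training split: {flat}")
    y_min, y_max = float(y[tr].min()), float(y[tr].max())
    if y_max - y_min <= 0:
        raise ParameterError("constant target on the training split")

    Xn = 2.0 * (X - x_min) / (x_max - x_min) - 1.0
    yn = 2.0 * (y - y_min) / (y_max - y_min) - 1.0
    y_scale2 = ((y_max - y_min) / 2.0) ** 2  # normalized->original MSE factor

    rng = np.random.default_rng(seed)
    W1 = rng.uniform(-0.5, 0.5, (n_hidden, d))
    b1 = rng.uniform(-0.5, 0.5, n_hidden)
    w2 = rng.uniform(-0.5, 0.5, n_hidden)
    b2 = float(rng.uniform(-0.5, 0.5))

    def mses(W1, b1, w2, b2):
        _, yh = _forward(Xn, W1, b1, w2, b2)
        e = yn - yh
        return tuple(float(np.mean(e[idx] ** 2)) * y_scale2 for idx in (tr, va, te))

    trace = {"train": [], "validation": [], "test": []}

    def record(vals):
        for k, v in zip(("train", "validation", "test"), vals):
            trace[k].append(v)

    record(mses(W1, b1, w2, b2))
    best_val = trace["validation"][0]
    best_epoch = 0
    best_params = _pack(W1, b1, w2, b2)

    mu = mu_init
    fails = 0
    n_params = n_hidden * d + 2 * n_hidden + 1
    eye = np.eye(n_params)
    Xtr, ytr = Xn[tr], yn[tr]

    for epoch in range(1, max_epochs + 1):
        z, yh = _forward(Xtr, W1, b1, w2, b2)
        r = ytr - yh
        sse = float(r @ r)
        if not np.isfinite(sse):
            raise TrainingError("non-finite training loss")
        # Jacobian of predictions w.r.t. parameters
        dz = (1.0 - z**2) * w2  # (n, h)
        J = np.empty((len(tr), n_params))
        J[:, : n_hidden * d] = (dz[:, :, None] * Xtr[:, None, :]).reshape(len(tr), -1)
        J[:, n_hidden * d : n_hidden * d + n_hidden] = dz
        J[:, n_hidden * d + n_hidden : n_hidden * d + 2 * n_hidden] = z
        J[:, -1] = 1.0
        JtJ = J.T @ J
        g = J.T @ r

        accepted = False
        while mu <= mu_max:
            try:
                step = np.linalg.solve(JtJ + mu * eye, g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            p_new = _pack(W1, b1, w2, b2) + step
            W1n, b1n, w2n, b2n = _unpack(p_new, n_hidden, d)
            _, yh_new = _forward(Xtr, W1n, b1n, w2n, b2n)
            r_new = ytr - yh_new
            sse_new = float(r_new @ r_new)
            if np.isfinite(sse_new) and sse_new < sse:
                W1, b1, w2, b2 = W1n, b1n, w2n, float(b2n)
                mu = max(mu / 10.0, 1e-20)
                accepted = True
                break
            mu *= 10.0
        if not accepted:
            break  # damping exhausted: converged

        record(mses(W1, b1, w2, b2))
        val = trace["validation"][-1]
        if val < best_val:
            best_val = val
            best_epoch = epoch
            best_params = _pack(W1, b1, w2, b2)
            fails = 0
        else:
            fails += 1
            if fails > patience:
                break

    W1, b1, w2, b2 = _unpack(best_params, n_hidden, d)
    return FFNNModel(
        input_names=list(names),
        W1=W1, b1=b1, w2=w2, b2=float(b2),
        x_min=x_min, x_max=x_max, y_min=y_min, y_max=y_max,
        trace=trace, best_epoch=best_epoch,
    )


def hidden_layer_sweep(
    features,
    ages,
    hidden_range=range(1, 21),
    split: SplitSpec = SplitSpec(),
    seeds: dict[int, int] | int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Refit the network across hidden-layer sizes.

    Returns one row per size with the test MSE, best-validation epoch, and
    Pearson r on the train/validation/test/all splits.  ``seeds`` is either a
    single seed used for every size or a mapping size -> seed.
    """
    if isinstance(features, pd.DataFrame):
        y = np.asarray(ages, dtype=float)
    else:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        y = np.asarray(ages, dtype=float)
    rows = []
    for h in hidden_range:
        seed = seeds[h] if isinstance(seeds, dict) else int(seeds)
        model = fit_ffnn(features, y, n_hidden=h, split=split, seed=seed, **fit_kwargs)
        pred = model.predict(features)
        tr, va, te = split_indices(len(y), split)
        rows.append(
            {
                "n_hidden": h,
                "mse_test": float(np.mean((pred[te] - y[te]) ** 2)),
                "best_epoch": model.best_epoch,
                "r_train": pearson_r(pred[tr], y[tr]),
                "r_validation": pearson_r(pred[va], y[va]),
                "r_test": pearson_r(pred[te], y[te]),
                "r_all": pearson_r(pred, y),
            }
        )
    return pd.DataFrame(rows)
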