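"""Linear age models: the published two-variable equation and stepwise
ordinary-least-squares refitting.

The published model predicts chronological age from the Aging Index and the
third-derivative sum:

    age = 109.65 + 22.16 * AI - 0.05 * sum_tdppg_e4

Refitting uses forward-entry / backward-removal stepwise OLS over the ten
candidate features, with conventional significance thresholds (enter at
p < 0.05, remove at p > 0.10).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ParameterError

__all__ = ["LinearAgeModel", "published_model", "fit_linear_stepwise"]


@dataclass
class LinearAgeModel:
    """Intercept + per-feature coefficients (years per unit)."""

    intercept: float
    coefficients: dict[str, float]
    fit_stats: dict = field(default_factory=dict)

    @property
    def selected_features(self) -> list[str]:
        return list(self.coefficients)

    def predict(self, features) -> np.ndarray:
        """Predict ages from a DataFrame or mapping of feature arrays/values."""
        if isinstance(features, dict):
            features = pd.DataFrame({k: np.atleast_1d(v) for k, v in features.items()})
        missing = [k for k in self.coefficients if k not in features.columns]
        if missing:
            raise ParameterError(f"missing features: {missing}")
        y = np.full(len(features), self.intercept, dtype=float)
        for name, coef in self.coefficients.items():
            y += coef * features[name].to_numpy(dtype=float)
        return y

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"kind": "linear", "intercept": self.intercept,
                 "coefficients": self.coefficients, "fit_stats": self.fit_stats},
                indent=1, default=float,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearAgeModel":
        d = json.loads(Path(path).read_text())
        return cls(d["intercept"], d["coefficients"], d.get("fit_stats", {}))


def published_model() -> LinearAgeModel:
    """The fixed two-variable linear age model (AI + third-derivative sum)."""
    return LinearAgeModel(
        intercept=109.65,
        coefficients={"AI": 22.16, "sum_tdppg_e4": -0.05},
        fit_stats={"adjusted_r2": 0.46, "source": "published"},
    )


def _ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def fit_linear_stepwise(
    features: pd.DataFrame,
    ages,
    candidates: list[str] | None = None,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 100,
) -> LinearAgeModel:
    """Forward-entry / backward-removal stepwise OLS.

    At each step the candidate with the smallest entry p-value below
    ``p_enter`` joins the model, then any included variable with p-value
    above ``p_remove`` leaves.  With ``p_enter < p_remove`` the procedure
    cannot cycle and terminates.
    """
    if not p_enter < p_remove:
        raise ParameterError("p_enter must be smaller than p_remove to guarantee termination")
    if candidates is None:
        candidates = [c for c in features.columns if c not in ("subject_id", "age")]
    y = np.asarray(ages, dtype=float)
    n = len(y)
    if n <= len(candidates) + 2:
        raise ParameterError(
            f"need more subjects ({n}) than candidates + 2 ({len(candidates) + 2})"
        )
    X_all = features[candidates].astype(float)
    if X_all.isna().any().any() or not np.isfinite(y).all():
        raise ParameterError("missing or non-finite values in features/ages")

    if float(np.std(y)) == 0.0:
        # degenerate target: every coefficient is 0/0; return intercept-only
        return LinearAgeModel(float(np.mean(y)), {}, {"adjusted_r2": 0.0, "n": n})

    included: list[str] = []
    for _ in range(max_steps):
        changed = False
        # forward entry
        best_p, best_var = np.inf, None
        for var in candidates:
            if var in included:
                continue
            res = _ols(y, X_all[included + [var]])
            p = res.pvalues.get(var, np.nan)
            if np.isfinite(p) and p < best_p:
                best_p, best_var = p, var
        if best_var is not None and best_p < p_enter:
            included.append(best_var)
            changed = True
        # backward removal
        while included:
            res = _ols(y, X_all[included])
            pvals = res.pvalues.drop("const", errors="ignore")
            worst = pvals.idxmax()
            if pvals[worst] > p_remove:
                included.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break

    res = _ols(y, X_all[included]) if included else _ols(y, X_all[[]])
    if included:
        rank = np.linalg.matrix_rank(sm.add_constant(X_all[included]).to_numpy())
        if rank < len(included) + 1:
            raise ParameterError("collinear design: selected features are rank deficient")
    coefs = {v: float(res.params[v]) for v in included}
    stats = {
        "adjusted_r2": float(res.rsquared_adj) if included else 0.0,
        "se": {k: float(res.bse[k]) for k in res.bse.index},
        "t": {k: float(res.tvalues[k]) for k in res.tvalues.index},
        "p": {k: float(res.pvalues[k]) for k in res.pvalues.index},
        "n": n,
    }
    return LinearAgeModel(float(res.params["const"]), coefs, stats)
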