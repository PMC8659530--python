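"""Run configuration: one human-readable YAML file driving the whole pipeline.

Every otherwise-silent default of the analysis chain is surfaced here as a
named key (filter order 4, pass band 0.4-9 Hz, sampling rate 250 Hz, test
fraction 0.20, 15 hidden neurons, ...).  Unknown keys are rejected so typos
fail loudly instead of silently running with defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ParameterError
from .features import FeatureConfig
from .ffnn import SplitSpec
from .preprocess import FilterSpec
from .simulate import CohortSpec

__all__ = ["ModelConfig", "RunConfig", "load_config", "config_hash"]


@dataclass
class ModelConfig:
    """Age-model choice and hyperparameters."""

    kind: str = "all"  # "published" | "stepwise" | "ffnn" | "all"
    p_enter: float = 0.05
    p_remove: float = 0.10
    n_hidden: int = 15
    max_epochs: int = 1000
    patience: int = 6
    mu_init: float = 1e-3

    def __post_init__(self) -> None:
        if self.kind not in ("published", "stepwise", "ffnn", "all"):
            raise ParameterError(f"unknown model kind {self.kind!r}")


@dataclass
class RunConfig:
    """Everything needed to reproduce a full run from a fixed seed."""

    out_dir: str = "runs/default"
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    filter: FilterSpec = field(default_factory=FilterSpec)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    split: SplitSpec = field(default_factory=SplitSpec)

    def __post_init__(self) -> None:
        # a single master seed governs cohort generation and the data split
        self.cohort = dataclasses.replace(self.cohort, seed=self.seed)
        self.split = dataclasses.replace(self.split, seed=self.seed)
        self.features = dataclasses.replace(self.features, filter_spec=self.filter)


_TUPLE_KEYS = {"band", "interval_window_ms", "age_range"}


def _build(cls, data: dict, path: str):
    """Construct dataclass ``cls`` from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ParameterError(f"config section {path!r} must be a mapping")
    allowed = {f.name for f in fields(cls)}
    unknown = sorted(set(data) - allowed)
    if unknown:
        raise ParameterError(
            f"unknown key(s) {unknown} in config section {path!r}; "
            f"allowed: {sorted(allowed)}"
        )
    kwargs = {
        k: tuple(v) if k in _TUPLE_KEYS and isinstance(v, list) else v
        for k, v in data.items()
    }
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a :class:`RunConfig` from YAML, or defaults when ``path`` is None."""
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ParameterError(f"config file {path} must contain a mapping")
        data = raw
    if overrides:
        data = {**data, **overrides}
    sections = {
        "cohort": CohortSpec,
        "filter": FilterSpec,
        "features": FeatureConfig,
        "model": ModelConfig,
        "split": SplitSpec,
    }
    allowed_top = {"out_dir", "seed", *sections}
    unknown = sorted(set(data) - allowed_top)
    if unknown:
        raise ParameterError(
            f"unknown top-level config key(s) {unknown}; allowed: {sorted(allowed_top)}"
        )
    kwargs: dict = {}
    for key in ("out_dir", "seed"):
        if key in data:
            kwargs[key] = data[key]
    for key, cls in sections.items():
        if key in data:
            kwargs[key] = _build(cls, data[key], key)
    return RunConfig(**kwargs)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if callable(obj):
        return getattr(obj, "__name__", repr(obj))
    return obj


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the full resolved configuration (provenance)."""
    canon = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
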