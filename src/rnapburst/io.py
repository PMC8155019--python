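"""Plain-text I/O: long-format trace CSV, correlation tables, configs."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .containers import CorrelationSet, TraceSet
from .model import RateParameters
from .synthetic import ExperimentConfig

__all__ = [
    "save_traces",
    "load_traces",
    "save_correlations",
    "load_params",
    "save_params",
    "load_experiment_config",
    "save_experiment_config",
]


def save_traces(traces: TraceSet, path: str | Path) -> None:
    traces.to_frame().to_csv(path, index=False)


def load_traces(path: str | Path) -> TraceSet:
    return TraceSet.from_frame(pd.read_csv(path))


def save_correlations(corr: CorrelationSet, path: str | Path) -> None:
    """CSV table of curves/SEM plus a JSON sidecar with scalars."""
    path = Path(path)
    corr.to_frame().to_csv(path, index=False)
    sidecar = {
        "gbar0": {f"{a}-{b}": v for (a, b), v in corr.gbar0.items()},
        "shot_noise_var": corr.shot_noise_var,
        "n_cells": corr.n_cells,
        "dt": corr.dt,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_params(path: str | Path) -> RateParameters:
    """Model config from YAML/JSON with keys omega, k_off, beta, ... extras."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return RateParameters.from_dict(data)


def save_params(params: RateParameters, path: str | Path, variant: str = "base") -> None:
    d = params.to_dict()
    d["variant"] = variant
    d["extras"] = d.pop("variant_extras")
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_experiment_config(path: str | Path) -> ExperimentConfig:
    return ExperimentConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def save_experiment_config(config: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
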