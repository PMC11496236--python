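"""Readers, writers and run configuration.

The canonical interchange format is a single long-format CSV with one row
per person-wave: ``person_id``, ``wave``, the indicator columns, covariate
columns (empty field = missing), an optional ``baseline`` flag column for
pooled data, and an optional ``class_truth`` column (simulation only).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datagen
from .errors import ValidationError
from .panel import INDICATORS, PanelDataset

logger = logging.getLogger(__name__)


def read_panel(path, indicators: list[str] | None = None) -> PanelDataset:
    """Read and validate a long-format panel CSV.

    Non-binary indicator cells are a hard error naming the offending rows;
    monotone-dropout violations are a warning; empty covariate fields parse
    as missing.
    """
    df = pd.read_csv(path)
    for col in ("person_id", "wave"):
        if col not in df.columns:
            raise ValidationError(f"missing required column: {col!r}")
    return PanelDataset(df, indicators=indicators, validate=True)


def write_panel(data: PanelDataset, path) -> None:
    """Write the panel as CSV; missing values become empty fields."""
    data.df.to_csv(path, index=False)


def missingness_report(data: PanelDataset) -> pd.DataFrame:
    """Missing-value counts per covariate column."""
    rows = [{"covariate": c,
             "n_missing": int(data.df[c].isna().sum()),
             "n_records": data.n_records}
            for c in data.covariate_names]
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Generator config serialization (flat key paths, matrices as nested lists)
# --------------------------------------------------------------------------

def config_to_yaml(config: datagen.GeneratorConfig, path) -> None:
    d = dataclasses.asdict(config)
    for k, v in list(d.items()):
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    d["covariate_spec"] = [
        {k: (v.tolist() if isinstance(v, np.ndarray) else v)
         for k, v in dataclasses.asdict(s).items()}
        for s in config.covariate_spec]
    d["indicator_names"] = list(config.indicator_names)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path) -> datagen.GeneratorConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    specs = [datagen.CovariateSpec(**s) for s in d.pop("covariate_spec", [])]
    return datagen.GeneratorConfig(covariate_spec=specs, **d)


# --------------------------------------------------------------------------
# Run configuration for the end-to-end pipeline
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one pipeline run needs; all randomness flows from ``seed``."""

    out_dir: str = "results/run"
    input_csv: str | None = None          # None -> simulate
    seed: int = 0
    k_min: int = 1
    k_max: int = 5
    k_fixed: int | None = None            # skip selection when set
    n_starts: int = 64
    start_iters: int = 250
    bootstrap_B: int = 0
    tol: float = 1e-8
    covariates: list[str] = field(default_factory=list)
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def setup_logging(out_dir: str | Path | None = None,
                  level: str = "INFO") -> None:
    """Structured stage logging, duplicated to console and file."""
    handlers = [logging.StreamHandler()]
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(Path(out_dir) / "run.log"))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers, force=True)


__all__ = ["read_panel", "write_panel", "missingness_report",
           "config_to_yaml", "config_from_yaml", "RunConfig",
           "setup_logging", "INDICATORS"]
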