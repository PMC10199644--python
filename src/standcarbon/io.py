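"""Input loading, validation and run configuration.

All tabular inputs are plain CSV with the column conventions documented in
``data/DATA_DICTIONARY.md``; fitted models serialise to JSON; configuration is
YAML or JSON.  Loading runs the structural invariant checks (metric orderings,
AWEN partition sums, positive stocks) and reports hard errors with row
context.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import CELL_SIDE, EPOCH_END, EPOCH_START
from .litter import awen_partition_frame, turnover_fractions_frame

__all__ = ["RunConfig", "InputBundle", "load_inputs", "validate_metrics", "load_config"]


@dataclass
class RunConfig:
    """Paths, constants and policy flags for a full run."""

    cells: str = "cells.csv"
    stands: str = "stands.csv"
    plots: str = "plots.csv"
    trees: str = "trees.csv"
    climate: str = "climate.csv"
    disturbance: str = "disturbance.csv"
    carbon_fraction: float = 0.5
    background_mortality: float = 0.004
    harvest_sw_extraction: float = 0.95
    inversion_tolerance: float = 1e-3
    cell_side: float = CELL_SIDE
    start_year: int = EPOCH_START
    end_year: int = EPOCH_END
    bias_correction: bool = False
    disturbed_constant_mortality: bool = True
    seed: int = 1
    bootstrap_draws: int = 1000
    turnover: dict | None = None
    awen: dict | None = None

    def __post_init__(self):
        for name in ("carbon_fraction", "background_mortality", "harvest_sw_extraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.start_year < self.end_year:
            raise ValueError("timeframe start must precede end")


def load_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    doc = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
    return RunConfig(**doc)


def validate_metrics(frame: pd.DataFrame, suffix: str = "") -> list[str]:
    """Check percentile/density ordering invariants; returns error strings."""
    errors = []
    pctl = [f"H_ALS_{p}{suffix}" for p in range(10, 100, 10)]
    dens = [f"D_ALS_{i}{suffix}" for i in range(1, 11)]
    if all(c in frame.columns for c in pctl):
        vals = frame[pctl].to_numpy()
        bad = np.where((np.diff(vals, axis=1) < -1e-9).any(axis=1))[0]
        errors += [f"row {i}: height percentiles not non-decreasing" for i in bad[:20]]
    if all(c in frame.columns for c in dens):
        vals = frame[dens].to_numpy()
        bad = np.where((np.diff(vals, axis=1) > 1e-9).any(axis=1))[0]
        errors += [f"row {i}: cumulative densities not non-increasing" for i in bad[:20]]
        out = np.where(((vals < -1e-12) | (vals > 1 + 1e-12)).any(axis=1))[0]
        errors += [f"row {i}: density outside [0, 1]" for i in out[:20]]
    return errors


@dataclass
class InputBundle:
    cells: pd.DataFrame
    stands: pd.DataFrame
    plots: pd.DataFrame
    trees: pd.DataFrame | None
    climate: pd.DataFrame
    climate_ref: tuple
    disturbance: pd.DataFrame | None
    turnover: pd.DataFrame = field(default_factory=turnover_fractions_frame)
    awen: pd.DataFrame = field(default_factory=awen_partition_frame)


def load_inputs(config: RunConfig, base: str | Path = ".") -> InputBundle:
    """Read and validate every input table; raises with row context on error."""
    base = Path(base)
    errors: list[str] = []

    cells = pd.read_csv(base / config.cells)
    stands = pd.read_csv(base / config.stands)
    plots = pd.read_csv(base / config.plots)
    climate = pd.read_csv(base / config.climate)
    trees = None
    if (base / config.trees).exists():
        trees = pd.read_csv(base / config.trees)
    disturbance = None
    if (base / config.disturbance).exists():
        disturbance = pd.read_csv(base / config.disturbance)

    for year in (config.start_year, config.end_year):
        errors += [f"cells ({year}): {e}" for e in validate_metrics(cells, f"_{year}")]
    errors += [f"plots: {e}" for e in validate_metrics(plots)]
    need = {"stand_id", "SI", "AGE", "SP", "area_ha"} - set(stands.columns)
    if need:
        errors.append(f"stands: missing columns {sorted(need)}")
    need = {"year", "precipitation", "temperature", "amplitude"} - set(climate.columns)
    if need:
        errors.append(f"climate: missing columns {sorted(need)}")
    else:
        span = set(range(config.start_year, config.end_year)) - set(climate["year"])
        if span:
            errors.append(f"climate: missing years {sorted(span)}")
        if (climate["precipitation"] < 0).any():
            errors.append("climate: negative precipitation")

    turnover = turnover_fractions_frame(config.turnover)
    try:
        awen = awen_partition_frame(config.awen)
    except ValueError as exc:
        raise ValueError(f"awen: {exc}") from exc
    if errors:
        raise ValueError("input validation failed:\n  " + "\n  ".join(errors))

    window = climate[(climate["year"] >= 1957) & (climate["year"] <= 2000)]
    if len(window):
        ref = tuple(float(window[c].mean())
                    for c in ("precipitation", "temperature", "amplitude"))
    else:
        ref = tuple(float(climate[c].mean())
                    for c in ("precipitation", "temperature", "amplitude"))
    return InputBundle(cells, stands, plots, trees, climate, ref,
                       disturbance, turnover, awen)
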