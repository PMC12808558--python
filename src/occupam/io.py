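"""Schema-validated CSV readers/writers and the run configuration.

All tabular interchange is plain CSV with documented headers; encounter
histories are written in a tidy long layout (site, year, week, y,
effort_hours) so they diff cleanly, plus a wide layout with one
year-week column per occasion.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detections import EncounterHistory

__all__ = [
    "RunConfig",
    "read_predictions",
    "read_deployments",
    "read_callbacks",
    "read_cells",
    "read_burns",
    "write_history",
    "read_history",
    "load_reference_effort_table",
]

SCHEMAS = {
    "predictions": ["cell_id", "aru_id", "night", "segment_start",
                    "call_type", "confidence"],
    "deployments": ["aru_id", "cell_id", "x", "y", "start_night",
                    "end_night", "nightly_hours"],
    "callbacks": ["x", "y", "night"],
    "cells": ["cell_id", "forest_id", "northing", "elevation", "canopy_height"],
    "burns": ["cell_id", "fire_year", "fraction"],
}

OPTIONAL = {"predictions": ["validated"], "cells": ["easting"]}


def _read(path, kind: str, date_cols=()) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = SCHEMAS[kind]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} file {path} is missing required "
                         f"column(s): {missing}")
    known = set(required) | set(OPTIONAL.get(kind, []))
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"{kind} file has unknown column(s) {unknown}; ignored",
                      RuntimeWarning)
    for c in date_cols:
        df[c] = pd.to_datetime(df[c]).dt.date
    return df


def read_predictions(path) -> pd.DataFrame:
    return _read(path, "predictions", date_cols=("night",))


def read_deployments(path) -> pd.DataFrame:
    return _read(path, "deployments", date_cols=("start_night", "end_night"))


def read_callbacks(path) -> pd.DataFrame:
    return _read(path, "callbacks", date_cols=("night",))


def read_cells(path) -> pd.DataFrame:
    return _read(path, "cells")


def read_burns(path) -> pd.DataFrame:
    return _read(path, "burns")


def write_history(hist: EncounterHistory, out_dir) -> dict:
    """Write long and wide encounter-history CSVs; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    long = hist.to_long()
    long_path = out_dir / "history_long.csv"
    long.to_csv(long_path, index=False)
    wide = long.pivot_table(index="site", columns=["year", "week"], values="y",
                            dropna=False)
    wide.columns = [f"y{y}_w{w:02d}" for y, w in wide.columns]
    wide_path = out_dir / "history_wide.csv"
    wide.to_csv(wide_path)
    return {"long": str(long_path), "wide": str(wide_path)}


def read_history(long_path) -> EncounterHistory:
    df = pd.read_csv(long_path)
    sites = sorted(df["site"].unique())
    years = sorted(df["year"].unique())
    weeks = sorted(df["week"].unique())
    si = {s: i for i, s in enumerate(sites)}
    yi = {y: i for i, y in enumerate(years)}
    wi = {w: i for i, w in enumerate(weeks)}
    Y = np.full((len(sites), len(years), len(weeks)), np.nan)
    eff = np.zeros_like(Y)
    Y[df["site"].map(si), df["year"].map(yi), df["week"].map(wi)] = df["y"]
    eff[df["site"].map(si), df["year"].map(yi), df["week"].map(wi)] = df["effort_hours"]
    hist = EncounterHistory(Y=Y, effort=eff, site_ids=list(sites),
                            years=[int(y) for y in years],
                            weeks=[int(w) for w in weeks])
    hist.validate()
    return hist


def load_reference_effort_table() -> pd.DataFrame:
    """Published survey-effort and detection summary (forest x year).

    Columns: forest, year, arus, grid_cells, survey_hours, detections.
    Per-forest rows plus ``All forests`` totals from the reference
    monitoring program; used for internal-consistency checks.
    """
    with resources.files("occupam").joinpath("data/effort_table.csv").open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline configuration; defaults match the target study design."""

    seed: int = 0
    threshold: float = 0.989
    min_nights: int = 2
    cbi_threshold: float = 2.25
    season_start: str = "04-01"
    n_weeks: int = 18
    chains: int = 3
    iter: int = 1500
    warmup: int = 750
    n_walkers: int | None = None
    prior: dict = field(default_factory=lambda: {
        "beta_sd": 2.5, "mu_sd": 5.0, "sigma_scale": 2.5})
    simulate: dict = field(default_factory=lambda: {
        "n_cells": 200, "n_forests": 7, "years": [2021, 2022, 2023, 2024],
        "fire_rate": 5.5, "fp_rate": 0.05, "n_callbacks": 20,
        "n_arus": 2, "sigma": 0.5})
    paths: dict = field(default_factory=dict)
    out_dir: str = "runs/latest"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            warnings.warn(f"unknown config keys ignored: {sorted(unknown)}",
                          RuntimeWarning)
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
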