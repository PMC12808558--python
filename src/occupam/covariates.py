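"""Standardized design matrices for the four occupancy submodels.

Covariates follow the study design they emulate: initial occupancy is
predicted by canopy height, latitude-residualized elevation (linear and
quadratic), northing (linear and quadratic) and the cumulative
proportion of the cell burned at high severity; colonization and
extinction by the time-varying burned proportion plus transition-year
fixed effects; detection by log weekly recording hours, a quadratic in
date, and year fixed effects.  Every continuous column is centered and
scaled over the estimation set, with the scaling recorded so new data
can be projected onto the same scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "DesignSet",
    "residualize_elevation",
    "classify_high_severity",
    "cumulative_high_severity",
    "cumulative_hs_matrix",
    "build_state_design",
    "build_detection_design",
    "build_design",
    "standardize",
    "unstandardize",
]

CBI_HIGH_SEVERITY = 2.25
CBI_RANGE = (0.0, 3.0)
FIRE_START_YEAR = 1985


@dataclass
class DesignSet:
    """Covariate matrices plus grouping indices for model fitting.

    ``X_gamma``/``X_eps`` are (sites, transitions, k); transitions are
    labeled by their start year with the first year as reference level.
    ``X_p`` is (sites, years, weeks, k); entries for unsurveyed weeks are
    zero-filled and masked out by the likelihood via the encounter
    history's missingness.
    """

    X_psi: np.ndarray
    X_gamma: np.ndarray
    X_eps: np.ndarray
    X_p: np.ndarray
    forest_index: np.ndarray
    n_forests: int
    psi_cols: list
    trans_cols: list
    p_cols: list
    years: list
    site_ids: list = field(default_factory=list)
    scaling: dict = field(default_factory=dict)
    prop_hs: np.ndarray | None = None  # raw (sites, years) cumulative proportions


def standardize(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return (np.asarray(x, dtype=float) - mean) / (sd if sd > 0 else 1.0)


def unstandardize(z: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return np.asarray(z, dtype=float) * (sd if sd > 0 else 1.0) + mean


def _fit_scale(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    return float(np.mean(x)), float(np.std(x))


# ---------------------------------------------------------------------------
# elementary covariate operations
# ---------------------------------------------------------------------------

def residualize_elevation(cells: pd.DataFrame) -> np.ndarray:
    """Residuals of an OLS regression of elevation on northing.

    Removes the broad north-south elevation gradient so the elevation
    covariate measures local position rather than latitude.
    """
    northing = cells["northing"].to_numpy(float)
    elev = cells["elevation"].to_numpy(float)
    if len(cells) < 3 or np.unique(northing).size < 2:
        raise ValueError("elevation residualization needs >= 3 cells with "
                         "varying northing")
    X = np.column_stack([np.ones_like(northing), northing])
    coef, *_ = np.linalg.lstsq(X, elev, rcond=None)
    return elev - X @ coef


def classify_high_severity(cbi_values: np.ndarray,
                           threshold: float = CBI_HIGH_SEVERITY) -> np.ndarray:
    """Boolean high-severity layer: composite burn index >= threshold."""
    cbi = np.asarray(cbi_values, dtype=float)
    if np.any(cbi < CBI_RANGE[0]) or np.any(cbi > CBI_RANGE[1]):
        warnings.warn("CBI values outside [0, 3] clamped", RuntimeWarning)
        cbi = np.clip(cbi, *CBI_RANGE)
    return cbi >= threshold


def cumulative_high_severity(burn_layers, cell, monitoring_year: int,
                             start_year: int = FIRE_START_YEAR) -> float:
    """Proportion of a cell burned at high severity before a season.

    Accumulates fires with ``start_year <= fire_year < monitoring_year``
    (the monitoring year's own fires are excluded).  With per-pixel
    boolean masks the proportion is the exact pixel union; with scalar
    per-fire fractions overlap is unknowable and the union is
    approximated as 1 - prod(1 - fraction_f), which is exact whenever
    fires do not overlap.
    """
    if monitoring_year <= start_year:
        raise ValueError("monitoring_year must exceed start_year")
    if isinstance(burn_layers, pd.DataFrame):
        sub = burn_layers[(burn_layers["cell_id"] == cell)
                          & (burn_layers["fire_year"] >= start_year)
                          & (burn_layers["fire_year"] < monitoring_year)]
        fr = sub["fraction"].to_numpy(float)
        if np.any(fr < 0):
            raise ValueError("negative burned fractions")
        if np.any(fr > 1):
            raise ValueError("burned fractions exceed 1")
        return float(1.0 - np.prod(1.0 - fr))
    # mapping cell -> list of (fire_year, boolean pixel mask)
    layers = burn_layers.get(cell, [])
    union = None
    for fire_year, mask in layers:
        if not start_year <= fire_year < monitoring_year:
            continue
        mask = np.asarray(mask, dtype=bool)
        union = mask.copy() if union is None else (union | mask)
    if union is None:
        return 0.0
    return float(union.mean())


def cumulative_hs_matrix(burns: pd.DataFrame, cell_ids: list,
                         eval_years: list, start_year: int = FIRE_START_YEAR) -> np.ndarray:
    """Vectorized ``cumulative_high_severity`` over cells x years."""
    out = np.zeros((len(cell_ids), len(eval_years)))
    if burns is None or not len(burns):
        return out
    if np.any(burns["fraction"].to_numpy(float) < 0):
        raise ValueError("negative burned fractions")
    ci = {c: k for k, c in enumerate(cell_ids)}
    for t, y in enumerate(eval_years):
        sub = burns[(burns["fire_year"] >= start_year) & (burns["fire_year"] < y)]
        if not len(sub):
            continue
        log_surv = np.zeros(len(cell_ids))
        for c, fr in zip(sub["cell_id"], sub["fraction"].astype(float)):
            if c in ci:
                log_surv[ci[c]] += np.log1p(-min(fr, 1.0 - 1e-12))
        out[:, t] = 1.0 - np.exp(log_surv)
    return out


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

def _forest_codes(cells: pd.DataFrame) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(cells["forest_id"], sort=True)
    return codes.astype(int), len(uniques)


def build_state_design(cells: pd.DataFrame, burns: pd.DataFrame | None,
                       years: list, scaling: dict | None = None) -> dict:
    """Initial-occupancy / colonization / extinction design pieces.

    ``years`` are the monitored seasons; the transition starting in year
    ``t`` carries the burned proportion accumulated through fire seasons
    strictly before ``t`` (fires during the transition's start year act
    from the following transition on).
    """
    years = list(years)
    T = len(years)
    elev_res = residualize_elevation(cells)
    canopy = cells["canopy_height"].to_numpy(float)
    northing = cells["northing"].to_numpy(float)
    prop_hs = cumulative_hs_matrix(burns, list(cells["cell_id"]), years)

    fit = scaling is None
    scaling = dict(scaling or {})

    def col(name, x):
        if fit:
            scaling[name] = _fit_scale(x)
        return standardize(x, *scaling[name])

    z_can = col("canopy", canopy)
    z_elev = col("elev", elev_res)
    z_lat = col("lat", northing)
    z_hs0 = col("prop_hs_psi", prop_hs[:, 0])
    X_psi = np.column_stack([z_can, z_elev, z_elev ** 2, z_lat, z_lat ** 2, z_hs0])
    psi_cols = ["canopy", "elev", "elev2", "lat", "lat2", "prop_hs"]

    trans_years = years[:-1] if T > 1 else []
    hs_trans = prop_hs[:, :max(T - 1, 0)]
    if fit and T > 1:
        scaling["prop_hs_trans"] = _fit_scale(hs_trans.ravel())
    z_hs = (standardize(hs_trans, *scaling["prop_hs_trans"])
            if T > 1 else np.zeros((len(cells), 0)))
    trans_cols = ["prop_hs"] + [f"year_{y}" for y in trans_years[1:]]
    n_tr = max(T - 1, 0)
    X_tr = np.zeros((len(cells), n_tr, len(trans_cols)))
    if n_tr:
        X_tr[:, :, 0] = z_hs
        for k, y in enumerate(trans_years[1:]):
            X_tr[:, trans_years.index(y), 1 + k] = 1.0

    forest_index, n_forests = _forest_codes(cells)
    return {"X_psi": X_psi, "X_gamma": X_tr, "X_eps": X_tr.copy(),
            "psi_cols": psi_cols, "trans_cols": trans_cols,
            "forest_index": forest_index, "n_forests": n_forests,
            "scaling": scaling, "prop_hs": prop_hs}


def _week_midpoint_doy(year: int, week: int, season_start: str) -> int:
    m, d = (int(v) for v in season_start.split("-"))
    mid = date(year, m, d) + timedelta(days=7 * (week - 1) + 3)
    return mid.timetuple().tm_yday


def build_detection_design(effort: np.ndarray, years: list,
                           season_start: str = "04-01",
                           scaling: dict | None = None) -> dict:
    """Detection design: log weekly hours, quadratic date, year dummies."""
    effort = np.asarray(effort, dtype=float)
    n, T, J = effort.shape
    years = list(years)
    surveyed = effort > 0

    log_h = np.zeros_like(effort)
    log_h[surveyed] = np.log(effort[surveyed])
    doy = np.array([[_week_midpoint_doy(y, j + 1, season_start) for j in range(J)]
                    for y in years], dtype=float)         # (T, J)
    doy_full = np.broadcast_to(doy, (n, T, J))

    fit = scaling is None
    scaling = dict(scaling or {})
    if fit:
        scaling["log_hours"] = _fit_scale(log_h[surveyed])
        scaling["date"] = _fit_scale(doy_full[surveyed])
    z_h = np.where(surveyed, standardize(log_h, *scaling["log_hours"]), 0.0)
    z_d = np.where(surveyed, standardize(doy_full, *scaling["date"]), 0.0)

    p_cols = ["log_hours", "date", "date2"] + [f"year_{y}" for y in years[1:]]
    X_p = np.zeros((n, T, J, len(p_cols)))
    X_p[:, :, :, 0] = z_h
    X_p[:, :, :, 1] = z_d
    X_p[:, :, :, 2] = z_d ** 2
    for k, y in enumerate(years[1:]):
        X_p[:, years.index(y), :, 3 + k] = 1.0
    return {"X_p": X_p, "p_cols": p_cols, "scaling": scaling}


def build_design(cells: pd.DataFrame, burns: pd.DataFrame | None,
                 history, season_start: str = "04-01",
                 scaling: dict | None = None) -> DesignSet:
    """Full :class:`DesignSet` aligned with an encounter history.

    ``cells`` must cover every site in ``history``; rows are reordered to
    the history's site order.  Passing a previously recorded ``scaling``
    projects the new data onto the original scale instead of refitting.
    """
    cells = cells.set_index("cell_id", drop=False).loc[history.site_ids].reset_index(drop=True)
    surveyed_any = history.effort > 0
    if np.any(~np.isnan(history.Y) & ~surveyed_any):
        raise ValueError("non-missing observation with zero effort")

    state = build_state_design(cells, burns, history.years, scaling=scaling)
    det = build_detection_design(history.effort, history.years, season_start,
                                 scaling=scaling)
    merged_scaling = {**state["scaling"], **det["scaling"]}
    return DesignSet(
        X_psi=state["X_psi"], X_gamma=state["X_gamma"], X_eps=state["X_eps"],
        X_p=det["X_p"], forest_index=state["forest_index"],
        n_forests=state["n_forests"], psi_cols=state["psi_cols"],
        trans_cols=state["trans_cols"], p_cols=det["p_cols"],
        years=list(history.years), site_ids=list(history.site_ids),
        scaling=merged_scaling, prop_hs=state["prop_hs"],
    )
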