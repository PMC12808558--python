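"""Posterior-derived occupancy trajectories and trend statistics.

Trajectories are the *projected* (unconditional) kind: per posterior
draw, initial occupancy comes from the initial submodel and subsequent
years follow psi_{t+1} = psi_t (1 - eps_t) + (1 - psi_t) gamma_t,
without conditioning on the observed histories.  Trends are summarized
by the mean annual rate of change lambda-bar — the arithmetic mean over
intervals of the ratio of successive mean occupancies, computed per
draw — and by the probability of direction (PD), the posterior fraction
on one side of a reference value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import DesignSet
from .model import ParamVector, PosteriorDraws, link_probs

__all__ = [
    "TrendSummary",
    "project_occupancy",
    "conditional_occupancy_weight",
    "group_trajectory",
    "fire_strata",
    "lambda_bar",
    "prob_direction",
    "cumulative_detection",
    "cv_summary",
]


@dataclass
class TrendSummary:
    """Per-group posterior summary of the occupancy trajectory."""

    group_id: str
    years: list
    psi_mean: np.ndarray
    psi_lo: np.ndarray
    psi_hi: np.ndarray
    lambda_t_draws: np.ndarray
    lambda_bar_draws: np.ndarray
    lambda_bar_mean: float
    lambda_bar_lo: float
    lambda_bar_hi: float
    pd_trend: float            # probability of the dominant trend direction
    trend_direction: str       # "decline" / "increase" / "flat"
    cv_mean: float
    n_cells: int = 0
    psi_group_draws: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": self.group_id, "year": self.years,
            "mean": self.psi_mean, "lo95": self.psi_lo, "hi95": self.psi_hi,
        })


def _as_flat_draws(draws) -> np.ndarray:
    if isinstance(draws, PosteriorDraws):
        return draws.flat()
    return np.asarray(draws, dtype=float)


def project_occupancy(draws, design: DesignSet,
                      template: ParamVector | None = None,
                      n_years: int | None = None) -> np.ndarray:
    """Projected occupancy psi[draw, site, year].

    ``draws`` may be a :class:`PosteriorDraws`, a flat (m, dim) array
    (``template`` then required), or a single :class:`ParamVector`.
    """
    T = len(design.years)
    if n_years is not None and n_years > T:
        raise ValueError("requested projection beyond the design horizon")
    T_out = n_years or T

    if isinstance(draws, ParamVector):
        vec_list = [draws]
    else:
        if isinstance(draws, PosteriorDraws):
            template = draws.template
        flat = _as_flat_draws(draws)
        if template is None:
            raise ValueError("template ParamVector required for raw draw arrays")
        vec_list = [ParamVector.from_vector(v, template) for v in flat]

    n = design.X_psi.shape[0]
    out = np.empty((len(vec_list), n, T_out))
    for m, params in enumerate(vec_list):
        probs = link_probs(params, design)
        psi, gamma, eps = probs["psi"], probs["gamma"], probs["eps"]
        out[m, :, 0] = psi
        for t in range(1, T_out):
            prev = out[m, :, t - 1]
            out[m, :, t] = prev * (1 - eps[:, t - 1]) + (1 - prev) * gamma[:, t - 1]
    return out


def conditional_occupancy_weight(Y: np.ndarray) -> np.ndarray:
    """Indicator of site-years with a confirmed detection.

    Helper for the data-informed ("smoothed") trajectory variant: a
    site-year with >= 1 weekly detection is occupied with probability 1.
    """
    return np.nan_to_num(np.asarray(Y, dtype=float)).max(axis=2)


def lambda_bar(group_psi_draws: np.ndarray) -> dict:
    """Mean annual rate of change of a group-mean trajectory.

    ``group_psi_draws`` is (draws, years).  Per draw: lambda_t =
    psi_{t+1} / psi_t, and lambda-bar is the arithmetic mean of the
    T - 1 annual ratios.  Returns draws of both plus the probability of
    a declining trend (fraction of lambda-bar draws below 1).
    """
    psi = np.atleast_2d(np.asarray(group_psi_draws, dtype=float))
    if psi.shape[1] < 2:
        raise ValueError("lambda-bar requires >= 2 years")
    if np.any(psi <= 0):
        raise ValueError("mean occupancy of zero: lambda undefined")
    lam_t = psi[:, 1:] / psi[:, :-1]
    lam = lam_t.mean(axis=1)
    return {
        "lambda_t": lam_t,
        "lambda_bar": lam,
        "pd_decline": float(np.mean(lam < 1.0) + 0.5 * np.mean(lam == 1.0)),
    }


def prob_direction(draws_of_scalar: np.ndarray, reference: float = 0.0) -> float:
    """Probability of direction: posterior mass on the dominant side of
    ``reference``; draws exactly at the reference split evenly."""
    x = np.asarray(draws_of_scalar, dtype=float)
    if x.size == 0:
        raise ValueError("PD requires >= 1 draw")
    ties = np.mean(x == reference)
    above = np.mean(x > reference) + 0.5 * ties
    return float(max(above, 1.0 - above))


def cumulative_detection(p_weekly, n_weeks: int):
    """p* = 1 - (1 - p)^n: probability of >= 1 detection in n weeks."""
    p = np.asarray(p_weekly, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("weekly detection probability must lie in [0, 1]")
    if n_weeks < 0:
        raise ValueError("n_weeks must be >= 0")
    out = 1.0 - (1.0 - p) ** n_weeks
    return float(out) if np.isscalar(p_weekly) else out


def group_trajectory(psi_draws: np.ndarray, cell_groups: dict,
                     years: list | None = None) -> dict[str, TrendSummary]:
    """Summarize per-group mean occupancy trajectories and trends.

    ``psi_draws`` is (draws, sites, years); ``cell_groups`` maps group id
    to site indices (groups may partition or subset the sites).
    """
    m, n, T = psi_draws.shape
    years = list(years) if years is not None else list(range(T))
    out = {}
    for gid, idx in cell_groups.items():
        idx = np.asarray(idx)
        if idx.size == 0:
            raise ValueError(f"empty group {gid!r}")
        g = psi_draws[:, idx, :].mean(axis=1)          # (m, T)
        lo, hi = np.percentile(g, [2.5, 97.5], axis=0)
        lam = lambda_bar(g) if T >= 2 else None
        cv = float(np.mean(g.std(axis=0) / g.mean(axis=0)))
        if lam is not None:
            pd_dec = prob_direction(lam["lambda_bar"], reference=1.0)
            direction = ("decline" if np.mean(lam["lambda_bar"] < 1) >= 0.5
                         else "increase")
            summary = TrendSummary(
                group_id=str(gid), years=years, psi_mean=g.mean(axis=0),
                psi_lo=lo, psi_hi=hi, lambda_t_draws=lam["lambda_t"],
                lambda_bar_draws=lam["lambda_bar"],
                lambda_bar_mean=float(lam["lambda_bar"].mean()),
                lambda_bar_lo=float(np.percentile(lam["lambda_bar"], 2.5)),
                lambda_bar_hi=float(np.percentile(lam["lambda_bar"], 97.5)),
                pd_trend=pd_dec, trend_direction=direction, cv_mean=cv,
                n_cells=int(idx.size), psi_group_draws=g)
        else:
            summary = TrendSummary(
                group_id=str(gid), years=years, psi_mean=g.mean(axis=0),
                psi_lo=lo, psi_hi=hi, lambda_t_draws=np.empty((m, 0)),
                lambda_bar_draws=np.empty(m), lambda_bar_mean=np.nan,
                lambda_bar_lo=np.nan, lambda_bar_hi=np.nan, pd_trend=np.nan,
                trend_direction="flat", cv_mean=cv, n_cells=int(idx.size),
                psi_group_draws=g)
        out[str(gid)] = summary
    return out


def fire_strata(design: DesignSet, reference_year: int | None = None) -> dict:
    """Built-in grouper by cumulative high-severity burned proportion.

    Strata evaluated at ``reference_year`` (default: final monitoring
    year): ``unburned`` (exactly 0), ``hs_lt_0.5`` (0 < prop < 0.5) and
    ``hs_ge_0.5``.  Empty strata are omitted.
    """
    if design.prop_hs is None:
        raise ValueError("design carries no burned-proportion data")
    years = list(design.years)
    ref = reference_year if reference_year is not None else years[-1]
    t = years.index(ref)
    hs = design.prop_hs[:, t]
    groups = {
        "unburned": np.flatnonzero(hs == 0),
        "hs_lt_0.5": np.flatnonzero((hs > 0) & (hs < 0.5)),
        "hs_ge_0.5": np.flatnonzero(hs >= 0.5),
    }
    return {k: v for k, v in groups.items() if v.size}


def forest_groups(design: DesignSet) -> dict:
    """Built-in grouper: one group per national forest plus the region."""
    groups = {"region": np.arange(len(design.forest_index))}
    for f in range(design.n_forests):
        idx = np.flatnonzero(design.forest_index == f)
        if idx.size:
            groups[f"forest_{f + 1}"] = idx
    return groups


def cv_summary(group_psi_draws) -> float:
    """Mean posterior coefficient of variation across group-years.

    Accepts a (draws, years) array for one group or a dict of them.
    """
    if isinstance(group_psi_draws, dict):
        arrays = list(group_psi_draws.values())
    else:
        arrays = [np.atleast_2d(group_psi_draws)]
    cvs = []
    for g in arrays:
        g = np.atleast_2d(np.asarray(g, dtype=float))
        mean = g.mean(axis=0)
        if np.any(mean == 0):
            raise ValueError("zero posterior mean: CV undefined")
        cvs.append(g.std(axis=0) / mean)
    return float(np.concatenate(cvs).mean())
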