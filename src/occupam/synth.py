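"""Synthetic landscapes, fire histories, occupancy dynamics, detections
and classifier-style prediction tables.

The generator emulates a passive-acoustic-monitoring study frame:
hexagonal grid cells within national forests, recorders deployed for
roughly five weeks in the April-August breeding season, weekly detection
probability driven by recording effort, and a classifier that emits
confidence-scored predictions with a configurable false-positive rate.
Defaults reproduce the study conditions the package targets: baseline
initial occupancy around 0.3, annual colonization 0.12, extinction 0.39
and weekly detection probability near 0.6, with strong opposing effects
of high-severity fire on colonization and extinction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from . import covariates as cov
from .detections import EncounterHistory, expand_deployment_nights, CALL_TYPES
from .model import ParamVector, link_probs

__all__ = [
    "SimTruth",
    "paper_like_params",
    "gen_landscape",
    "gen_fire_history",
    "gen_deployments",
    "gen_callback_surveys",
    "simulate_occupancy",
    "simulate_detections",
    "gen_prediction_table",
]

SEASON_START = "04-01"
N_WEEKS = 18
NIGHT_HOURS = 10.0  # 20:00-06:00 analysis window


@dataclass
class SimTruth:
    """Latent occupancy truth: z (sites x years) plus the generating
    parameters, probabilities and seed."""

    z: np.ndarray
    params: ParamVector
    seed: int | None
    psi: np.ndarray
    gamma: np.ndarray
    eps: np.ndarray
    years: list = field(default_factory=list)
    cell_ids: list = field(default_factory=list)
    forest_index: np.ndarray | None = None


def paper_like_params(n_forests: int = 7, sigma: float = 0.5,
                      forest_jitter: bool = False,
                      rng: np.random.Generator | None = None,
                      n_years: int = 4) -> ParamVector:
    """Parameter preset matching the study's point estimates.

    Baselines (at covariate means): psi = 0.3, gamma = 0.12, eps = 0.39,
    weekly p = 0.6.  Coefficients are per standard deviation of the
    standardized covariates.  ``forest_jitter`` draws forest intercepts
    around the baselines with SD ``sigma``; otherwise all forests share
    the baseline.  Year-effect vectors are trimmed or zero-padded to the
    ``n_years`` monitored seasons.
    """
    mu = {"psi": special.logit(0.30), "gamma": special.logit(0.12),
          "eps": special.logit(0.39), "p": special.logit(0.60)}
    if forest_jitter:
        rng = rng or np.random.default_rng()
        alphas = {k: v + sigma * rng.standard_normal(n_forests)
                  for k, v in mu.items()}
    else:
        alphas = {k: np.full(n_forests, v) for k, v in mu.items()}

    def fit_len(values, k):
        out = np.zeros(k)
        m = min(k, len(values))
        out[:m] = values[:m]
        return out

    n_tr_dummies = max(n_years - 2, 0)
    n_p_dummies = max(n_years - 1, 0)
    return ParamVector(
        #         canopy  elev   elev2  lat    lat2   prop_hs
        beta_psi=[1.14, -0.24, -0.43, -0.89, -0.21, -0.19],
        beta_gamma=np.concatenate([[-0.77], fit_len([0.28, -0.36], n_tr_dummies)]),
        beta_eps=np.concatenate([[0.73], fit_len([-0.13, -0.15], n_tr_dummies)]),
        #        log_hours date  date2  then year effects (last year lower)
        beta_p=np.concatenate([[0.58, 0.01, -0.17],
                               fit_len([0.0, 0.0, -0.17], n_p_dummies)]),
        alpha_psi=alphas["psi"], alpha_gamma=alphas["gamma"],
        alpha_eps=alphas["eps"], alpha_p=alphas["p"],
        mu_psi=mu["psi"], mu_gamma=mu["gamma"], mu_eps=mu["eps"], mu_p=mu["p"],
        sigma_psi=sigma, sigma_gamma=sigma, sigma_eps=sigma, sigma_p=sigma,
    )


# ---------------------------------------------------------------------------
# landscape and fires
# ---------------------------------------------------------------------------

DEFAULT_LANDSCAPE = {
    "northing_range": (0.0, 400_000.0),   # m, projected
    "easting_range": (0.0, 100_000.0),
    "elev_base": 900.0,
    "elev_north_slope": 1.5e-3,           # m elevation per m northing
    "elev_sd": 350.0,
    "elev_range": (226.0, 3985.0),
    "canopy_mean": 22.0,
    "canopy_sd": 8.0,
}


def gen_landscape(n_cells: int, n_forests: int,
                  covariate_config: dict | None = None,
                  seed: int | None = None) -> pd.DataFrame:
    """Cell table with forests as contiguous blocks along northing."""
    if n_cells < 1 or n_forests < 1:
        raise ValueError("n_cells and n_forests must be >= 1")
    cfg = {**DEFAULT_LANDSCAPE, **(covariate_config or {})}
    rng = np.random.default_rng(seed)
    northing = np.sort(rng.uniform(*cfg["northing_range"], n_cells))
    easting = rng.uniform(*cfg["easting_range"], n_cells)
    elev = np.clip(cfg["elev_base"] + cfg["elev_north_slope"] * northing
                   + rng.normal(0, cfg["elev_sd"], n_cells), *cfg["elev_range"])
    canopy = np.clip(rng.normal(cfg["canopy_mean"], cfg["canopy_sd"], n_cells),
                     0.0, None)
    forest = np.concatenate([
        np.full(len(block), f + 1)
        for f, block in enumerate(np.array_split(np.arange(n_cells), n_forests))
    ])
    return pd.DataFrame({
        "cell_id": [f"c{k:04d}" for k in range(n_cells)],
        "forest_id": forest,
        "northing": northing,
        "easting": easting,
        "elevation": elev,
        "canopy_height": canopy,
    })


def gen_fire_history(cells: pd.DataFrame, years, fire_rate: float = 5.5,
                     severity_beta_params: tuple = (1.5, 5.0),
                     footprint_size_dist: tuple = ("lognormal", np.log(0.0025), 0.8),
                     seed: int | None = None) -> pd.DataFrame:
    """Poisson(fire_rate) fires per year over contiguous cell blocks.

    ``footprint_size_dist`` = ("lognormal", mu, sigma) draws each fire's
    footprint as a lognormal *fraction of the landscape* (default median
    0.25%, heavy upper tail for megafires); ("fixed", k, _) burns exactly
    k cells.  Each affected cell receives a newly-burned high-severity
    fraction drawn from Beta(``severity_beta_params``) (default mean
    0.23: most burned area is low/moderate severity); a cell may burn
    again in later years, with fractions accumulating via the complement
    product.  Over four decades at the defaults roughly half the cells
    never burn and a small minority accumulate >= 0.5 high severity.
    """
    if not len(cells):
        raise ValueError("empty cell table")
    years = list(years)
    if years and years != list(range(years[0], years[-1] + 1)):
        raise ValueError("years must be a contiguous range")
    if fire_rate < 0:
        raise ValueError("fire_rate must be >= 0")
    rng = np.random.default_rng(seed)
    order = np.argsort(cells["northing"].to_numpy())
    ids = cells["cell_id"].to_numpy()[order]
    rows = []
    a, b = severity_beta_params
    kind, m, s = footprint_size_dist
    for y in years:
        for _ in range(rng.poisson(fire_rate)):
            if kind == "lognormal":
                size = int(np.clip(np.round(rng.lognormal(m, s) * len(ids)),
                                   1, len(ids)))
            else:
                size = int(np.clip(m, 1, len(ids)))
            start = rng.integers(0, len(ids) - size + 1)
            for c in ids[start:start + size]:
                rows.append((c, y, float(rng.beta(a, b))))
    return pd.DataFrame(rows, columns=["cell_id", "fire_year", "fraction"])


# ---------------------------------------------------------------------------
# deployments and call-back surveys
# ---------------------------------------------------------------------------

def gen_deployments(cells: pd.DataFrame, years, n_arus: int = 2,
                    mean_nights: float = 34.0, sd_nights: float = 7.0,
                    nightly_hours: float = NIGHT_HOURS,
                    start_week_range: tuple = (1, 8),
                    seed: int | None = None) -> pd.DataFrame:
    """Recorder deployment log: ``n_arus`` per cell-year, ~5-week runs."""
    rng = np.random.default_rng(seed)
    rows = []
    for y in years:
        anchor = pd.Timestamp(f"{y}-{SEASON_START}")
        for _, c in cells.iterrows():
            for a in range(n_arus):
                start_week = rng.integers(start_week_range[0], start_week_range[1] + 1)
                offset = int((start_week - 1) * 7 + rng.integers(0, 7))
                n_nights = int(np.clip(np.round(rng.normal(mean_nights, sd_nights)),
                                       7, N_WEEKS * 7 - offset))
                start = anchor + pd.Timedelta(days=offset)
                end = start + pd.Timedelta(days=n_nights - 1)
                rows.append({
                    "aru_id": f"{c['cell_id']}_a{a}_{y}",
                    "cell_id": c["cell_id"],
                    "x": c["easting"] + rng.uniform(-800, 800),
                    "y": c["northing"] + rng.uniform(-800, 800),
                    "start_night": start.date(), "end_night": end.date(),
                    "nightly_hours": nightly_hours,
                })
    return pd.DataFrame(rows)


def gen_callback_surveys(deployments: pd.DataFrame, n_surveys: int,
                         seed: int | None = None) -> pd.DataFrame:
    """Call-back survey log co-located with random recorder-nights."""
    rng = np.random.default_rng(seed)
    nights, _ = expand_deployment_nights(deployments)
    locs = deployments.drop_duplicates("aru_id").set_index("aru_id")
    rows = []
    for _ in range(n_surveys):
        r = nights.iloc[rng.integers(0, len(nights))]
        loc = locs.loc[r["aru_id"]]
        rows.append({"x": float(loc["x"]) + rng.uniform(-500, 500),
                     "y": float(loc["y"]) + rng.uniform(-500, 500),
                     "night": pd.Timestamp(r["night"]).date()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# latent dynamics and detections
# ---------------------------------------------------------------------------

def _state_design_set(cells: pd.DataFrame, burns, years) -> "cov.DesignSet":
    state = cov.build_state_design(cells, burns, list(years))
    T = len(list(years))
    X_p = np.zeros((len(cells), T, 1, 1))
    return cov.DesignSet(
        X_psi=state["X_psi"], X_gamma=state["X_gamma"], X_eps=state["X_eps"],
        X_p=X_p, forest_index=state["forest_index"], n_forests=state["n_forests"],
        psi_cols=state["psi_cols"], trans_cols=state["trans_cols"],
        p_cols=["const"], years=list(years), site_ids=list(cells["cell_id"]),
        scaling=state["scaling"], prop_hs=state["prop_hs"])


def simulate_occupancy(cells: pd.DataFrame, burns, params: ParamVector,
                       years, seed: int | None = None) -> SimTruth:
    """Draw latent occupancy via the same design/link code used in fits.

    z[i, 0] ~ Bernoulli(psi_i); z[i, t+1] ~ Bernoulli(z (1 - eps) +
    (1 - z) gamma).
    """
    years = list(years)
    design = _state_design_set(cells, burns, years)
    probs = link_probs(_pad_params(params, design), design)
    psi, gamma, eps = probs["psi"], probs["gamma"], probs["eps"]
    rng = np.random.default_rng(seed)
    n, T = len(cells), len(years)
    z = np.empty((n, T), dtype=int)
    z[:, 0] = rng.random(n) < psi
    for t in range(1, T):
        pr = np.where(z[:, t - 1] == 1, 1.0 - eps[:, t - 1], gamma[:, t - 1])
        z[:, t] = rng.random(n) < pr
    return SimTruth(z=z, params=params, seed=seed, psi=psi, gamma=gamma,
                    eps=eps, years=years, cell_ids=list(cells["cell_id"]),
                    forest_index=design.forest_index)


def _pad_params(params: ParamVector, design) -> ParamVector:
    """Truncate/extend beta_p so state-only designs can reuse the links."""
    kp = design.X_p.shape[3]
    if len(params.beta_p) == kp:
        return params
    beta_p = np.zeros(kp)
    m = min(kp, len(params.beta_p))
    beta_p[:m] = params.beta_p[:m]
    import dataclasses
    return dataclasses.replace(params, beta_p=beta_p)


def simulate_detections(sim_truth: SimTruth, deployments: pd.DataFrame,
                        params: ParamVector, seed: int | None = None
                        ) -> tuple[pd.DataFrame, EncounterHistory]:
    """Nightly detection events plus the directly aggregated truth history.

    The detection submodel defines a weekly probability p; it is spread
    uniformly over the week's surveyed nights as q = 1 - (1-p)^(1/m) so
    that the chance of >= 1 detection night equals p.  Unoccupied
    cell-years produce no events.
    """
    nights, _ = expand_deployment_nights(deployments, SEASON_START, N_WEEKS)
    raw_years = pd.DatetimeIndex(pd.to_datetime(deployments["start_night"])).year
    bad = set(raw_years) - set(sim_truth.years)
    if bad:
        raise ValueError(f"deployment years outside the simulation: {sorted(bad)}")

    site_ids = list(sim_truth.cell_ids)
    years = list(sim_truth.years)
    si = {s: k for k, s in enumerate(site_ids)}
    yi = {y: k for k, y in enumerate(years)}
    n, T, J = len(site_ids), len(years), N_WEEKS

    effort = np.zeros((n, T, J))
    for (c, y, w), h in nights.groupby(["cell_id", "year", "week"])["hours"].sum().items():
        effort[si[c], yi[y], w - 1] = h

    det = cov.build_detection_design(effort, years, SEASON_START)
    forest_index = sim_truth.forest_index
    if forest_index is None:
        forest_index = _forest_from_truth(sim_truth, n)
    eta = (params.alpha_p[forest_index][:, None, None]
           + np.einsum("itjk,k->itj", det["X_p"], params.beta_p))
    p = special.expit(np.clip(eta, -35, 35))

    rng = np.random.default_rng(seed)
    # distinct survey nights per cell-week
    uniq = nights.drop_duplicates(["cell_id", "night"]).copy()
    uniq["i"] = uniq["cell_id"].map(si)
    uniq["t"] = uniq["year"].map(yi)
    m_nights = uniq.groupby(["i", "t", "week"])["night"].transform("count").to_numpy()
    ii = uniq["i"].to_numpy()
    tt = uniq["t"].to_numpy()
    jj = uniq["week"].to_numpy() - 1
    p_week = p[ii, tt, jj]
    q_night = 1.0 - (1.0 - p_week) ** (1.0 / m_nights)
    occupied = sim_truth.z[ii, tt] == 1
    detected = occupied & (rng.random(len(uniq)) < q_night)

    ev = uniq[detected][["cell_id", "aru_id", "night"]].reset_index(drop=True)
    ev["night"] = pd.to_datetime(ev["night"]).dt.date

    Y = np.where(effort > 0, 0.0, np.nan)
    for i_, t_, j_ in zip(ii[detected], tt[detected], jj[detected]):
        Y[i_, t_, j_] = 1.0
    truth = EncounterHistory(Y=Y, effort=effort, site_ids=site_ids, years=years)
    truth.validate()
    return ev, truth


def _forest_from_truth(sim_truth: SimTruth, n: int) -> np.ndarray:
    if len(sim_truth.params.alpha_p) == 1:
        return np.zeros(n, dtype=int)
    raise ValueError("simulate_detections needs sim_truth.forest_index for "
                     "multi-forest parameter vectors; attach it before calling")


# ---------------------------------------------------------------------------
# classifier-style predictions
# ---------------------------------------------------------------------------

def _default_tp_conf(rng, size):
    return rng.beta(60.0, 1.0, size)  # mass near 1, tail below threshold


def _default_fp_conf(rng, size):
    return rng.beta(30.0, 1.5, size)  # high-ish scores: survived pre-screening


def gen_prediction_table(events: pd.DataFrame, fp_rate: float = 0.0,
                         tp_confidence_dist=None, fp_confidence_dist=None,
                         callback_surveys: pd.DataFrame | None = None,
                         deployments: pd.DataFrame | None = None,
                         calls_per_event: int = 1,
                         seed: int | None = None) -> pd.DataFrame:
    """Classifier-style prediction table from true detection events.

    True events become predictions with confidences from
    ``tp_confidence_dist``; spurious predictions are injected at
    ``fp_rate`` per surveyed recorder-night (requires ``deployments``).
    When ``callback_surveys`` is given, injected false positives are
    additionally placed on recorder-nights within 1.5 km of a same-night
    survey, exercising the downstream exclusion filter.  ``validated``
    flags carry the ground truth for validation bookkeeping.
    """
    if fp_rate < 0:
        raise ValueError("fp_rate must be >= 0")
    rng = np.random.default_rng(seed)
    tp_dist = tp_confidence_dist or _default_tp_conf
    fp_dist = fp_confidence_dist or _default_fp_conf
    rows = []
    for _, e in events.iterrows():
        for _k in range(calls_per_event):
            rows.append({
                "cell_id": e["cell_id"], "aru_id": e["aru_id"],
                "night": e["night"],
                "segment_start": int(rng.integers(0, 36000 // 3) * 3),
                "call_type": CALL_TYPES[rng.integers(0, len(CALL_TYPES))],
                "confidence": float(np.clip(tp_dist(rng, 1)[0], 0.0, 1.0)),
                "validated": "true-positive",
            })
    if fp_rate > 0:
        if deployments is None:
            raise ValueError("deployments required to inject false positives")
        nights, _ = expand_deployment_nights(deployments)
        n_fp = rng.poisson(fp_rate, len(nights))
        for (idx, r), k in zip(nights.iterrows(), n_fp):
            for _j in range(k):
                rows.append({
                    "cell_id": r["cell_id"], "aru_id": r["aru_id"],
                    "night": pd.Timestamp(r["night"]).date(),
                    "segment_start": int(rng.integers(0, 36000 // 3) * 3),
                    "call_type": CALL_TYPES[rng.integers(0, len(CALL_TYPES))],
                    "confidence": float(np.clip(fp_dist(rng, 1)[0], 0.0, 1.0)),
                    "validated": "false-positive",
                })
    if callback_surveys is not None and len(callback_surveys) and deployments is not None:
        locs = deployments.drop_duplicates("aru_id")
        for _, cb in callback_surveys.iterrows():
            d = np.hypot(locs["x"].to_numpy(float) - float(cb["x"]),
                         locs["y"].to_numpy(float) - float(cb["y"]))
            near = locs[d <= 1500.0]
            if not len(near):
                continue
            a = near.iloc[rng.integers(0, len(near))]
            rows.append({
                "cell_id": a["cell_id"], "aru_id": a["aru_id"],
                "night": cb["night"],
                "segment_start": int(rng.integers(0, 36000 // 3) * 3),
                "call_type": CALL_TYPES[rng.integers(0, len(CALL_TYPES))],
                "confidence": float(np.clip(fp_dist(rng, 1)[0], 0.0, 1.0)),
                "validated": "false-positive",
            })
    cols = ["cell_id", "aru_id", "night", "segment_start", "call_type",
            "confidence", "validated"]
    return pd.DataFrame(rows, columns=cols)
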