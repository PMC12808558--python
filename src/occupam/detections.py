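"""From classifier prediction tables to weekly encounter histories.

The processing rules mirror a semi-automated bioacoustic pipeline:
predictions are thresholded on classifier confidence, reduced to the
best call type per 3-s audio segment, purged of records attributable to
broadcast call-back surveys (same night, within 1.5 km), and finally
aggregated into a sites x years x weeks detection/non-detection array
with matching survey-effort hours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CALL_TYPES",
    "EncounterHistory",
    "filter_predictions",
    "build_encounter_history",
    "validation_summary",
]

# tie-break precedence for equal-confidence call types within a segment
CALL_TYPES = ["four-note", "contact", "crow bark", "monkey hoot", "juvenile begging"]

CALLBACK_RADIUS_M = 1500.0
MAX_NIGHTLY_HOURS = 10.0  # the 20:00-06:00 analysis window


@dataclass
class EncounterHistory:
    """Weekly detection/non-detection data with matching effort.

    ``Y`` is (sites, years, weeks) with values {0.0, 1.0, NaN}; NaN marks
    weeks without acoustic monitoring.  ``effort`` has the same shape and
    holds recording hours summed across recorders in the cell-week.
    """

    Y: np.ndarray
    effort: np.ndarray
    site_ids: list = field(default_factory=list)
    years: list = field(default_factory=list)
    weeks: list = field(default_factory=list)

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        self.effort = np.asarray(self.effort, dtype=float)
        if not self.weeks:
            self.weeks = list(range(1, self.Y.shape[2] + 1))

    @property
    def n_sites(self) -> int:
        return self.Y.shape[0]

    @property
    def n_years(self) -> int:
        return self.Y.shape[1]

    @property
    def n_weeks(self) -> int:
        return self.Y.shape[2]

    def validate(self) -> None:
        if self.Y.shape != self.effort.shape:
            raise ValueError("Y and effort shapes differ")
        miss = np.isnan(self.Y)
        if np.any(miss != (self.effort <= 0)):
            raise ValueError("missing weeks must coincide with zero effort")
        vals = self.Y[~miss]
        if not np.isin(vals, [0.0, 1.0]).all():
            raise ValueError("Y values must be 0, 1 or missing")
        if np.any(self.effort < 0):
            raise ValueError("negative effort")

    def to_long(self) -> pd.DataFrame:
        i, t, j = np.indices(self.Y.shape)
        return pd.DataFrame({
            "site": np.asarray(self.site_ids)[i.ravel()] if self.site_ids else i.ravel(),
            "year": np.asarray(self.years)[t.ravel()] if self.years else t.ravel(),
            "week": np.asarray(self.weeks)[j.ravel()],
            "y": self.Y.ravel(),
            "effort_hours": self.effort.ravel(),
        })


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _check_confidence(preds: pd.DataFrame) -> None:
    conf = pd.to_numeric(preds["confidence"], errors="coerce")
    if conf.isna().any() or (conf < 0).any() or (conf > 1).any():
        raise ValueError("malformed confidence scores (must be numeric in [0, 1])")


def filter_predictions(preds: pd.DataFrame, threshold: float = 0.989,
                       callback_surveys: pd.DataFrame | None = None,
                       aru_locations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Reduce raw classifier predictions to validated detection events.

    Rules, in order: drop records flagged false-positive by manual
    validation; keep confidence >= ``threshold`` (inclusive); keep only
    the highest-confidence call type within each (recorder, night,
    segment), ties broken by the fixed ``CALL_TYPES`` precedence; drop
    records whose recorder sits within 1.5 km (inclusive) of a call-back
    survey conducted the same night.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    preds = preds.copy()
    if preds.empty:
        return preds.sort_index()
    _check_confidence(preds)
    preds["confidence"] = preds["confidence"].astype(float)

    if "validated" in preds.columns:
        preds = preds[preds["validated"] != "false-positive"]

    preds = preds[preds["confidence"] >= threshold]

    rank = {ct: k for k, ct in enumerate(CALL_TYPES)}
    preds = preds.assign(_rank=preds["call_type"].map(rank).fillna(len(CALL_TYPES)))
    preds = preds.sort_values(["aru_id", "night", "segment_start",
                               "confidence", "_rank"],
                              ascending=[True, True, True, False, True])
    preds = preds.groupby(["aru_id", "night", "segment_start"], as_index=False,
                          sort=False).head(1).drop(columns="_rank")

    if callback_surveys is not None and len(callback_surveys):
        if aru_locations is None:
            raise ValueError("ARU locations required to apply the call-back "
                             "survey exclusion")
        locs = aru_locations.drop_duplicates("aru_id").set_index("aru_id")
        missing = set(preds["aru_id"]) - set(locs.index)
        if missing:
            raise ValueError(f"no coordinates for ARUs: {sorted(missing)[:5]}")
        px = preds["aru_id"].map(locs["x"]).to_numpy(float)
        py = preds["aru_id"].map(locs["y"]).to_numpy(float)
        nights = preds["night"].to_numpy()
        drop = np.zeros(len(preds), dtype=bool)
        for _, cb in callback_surveys.iterrows():
            same_night = nights == cb["night"]
            if not same_night.any():
                continue
            d = np.hypot(px - float(cb["x"]), py - float(cb["y"]))
            drop |= same_night & (d <= CALLBACK_RADIUS_M)
        n_drop = int(drop.sum())
        if n_drop:
            log.info("call-back exclusion dropped %d predictions", n_drop)
        preds = preds[~drop]

    return preds.sort_values(["cell_id", "night"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# deployments -> nightly effort
# ---------------------------------------------------------------------------

def _season_start(year: int, season_start: str) -> np.datetime64:
    return np.datetime64(f"{year}-{season_start}")


def expand_deployment_nights(deployments: pd.DataFrame, season_start: str = "04-01",
                             n_weeks: int = 18) -> tuple[pd.DataFrame, int]:
    """One row per (recorder, night) with its season week index.

    Nights falling outside weeks 1..``n_weeks`` of their year's season
    are dropped; the count of dropped nights is returned alongside.
    """
    rows = []
    for _, d in deployments.iterrows():
        start = np.datetime64(pd.Timestamp(d["start_night"]).date())
        end = np.datetime64(pd.Timestamp(d["end_night"]).date())
        if start > end:
            raise ValueError(f"deployment for {d['aru_id']} has start > end")
        nights = np.arange(start, end + np.timedelta64(1, "D"))
        rows.append(pd.DataFrame({
            "aru_id": d["aru_id"], "cell_id": d["cell_id"], "night": nights,
            "hours": float(d["nightly_hours"]),
        }))
    if not rows:
        raise ValueError("empty deployment table")
    nights = pd.concat(rows, ignore_index=True)
    years = pd.DatetimeIndex(nights["night"]).year
    anchors = pd.to_datetime([f"{y}-{season_start}" for y in years])
    week = ((nights["night"].to_numpy("datetime64[D]")
             - anchors.to_numpy().astype("datetime64[D]")).astype(int) // 7) + 1
    nights["year"] = years
    nights["week"] = week
    in_season = (week >= 1) & (week <= n_weeks)
    n_dropped = int((~in_season).sum())
    if n_dropped:
        log.info("dropped %d recorder-nights outside the %d-week season",
                 n_dropped, n_weeks)
    return nights[in_season].reset_index(drop=True), n_dropped


# ---------------------------------------------------------------------------
# encounter history
# ---------------------------------------------------------------------------

def build_encounter_history(events: pd.DataFrame, deployments: pd.DataFrame,
                            season_start: str = "04-01", n_weeks: int = 18,
                            min_nights: int = 2) -> EncounterHistory:
    """Aggregate detection events into a weekly encounter history.

    Week ``j`` of site ``i`` in year ``t`` is coded 1 only when (a) at
    least one detection night falls in that week and (b) the cell-year
    has detections on >= ``min_nights`` distinct nights pooled across
    recorders and the whole season; surveyed weeks failing (b) are coded
    0, and weeks without any recording effort are missing.
    """
    nights, _ = expand_deployment_nights(deployments, season_start, n_weeks)
    site_ids = sorted(pd.unique(deployments["cell_id"]))
    years = sorted(pd.unique(nights["year"]))
    si = {s: k for k, s in enumerate(site_ids)}
    yi = {y: k for k, y in enumerate(years)}

    effort = np.zeros((len(site_ids), len(years), n_weeks))
    grp = nights.groupby(["cell_id", "year", "week"])["hours"].sum()
    for (c, y, w), h in grp.items():
        effort[si[c], yi[y], w - 1] = h

    Y = np.where(effort > 0, 0.0, np.nan)

    if len(events):
        ev = events.copy()
        ev["night"] = pd.to_datetime(ev["night"]).values.astype("datetime64[D]")
        ev = ev.drop_duplicates(["cell_id", "night"])
        ev_years = pd.DatetimeIndex(ev["night"]).year
        anchors = pd.to_datetime([f"{y}-{season_start}" for y in ev_years])
        week = ((ev["night"].to_numpy("datetime64[D]")
                 - anchors.to_numpy().astype("datetime64[D]")).astype(int) // 7) + 1
        ev["year"] = ev_years
        ev["week"] = week
        out = (week < 1) | (week > n_weeks)
        if out.any():
            log.info("dropped %d detection nights outside the season", int(out.sum()))
        ev = ev[~out]

        det_weeks = set()
        nights_per_cellyear: dict[tuple, set] = {}
        for _, r in ev.iterrows():
            if r["cell_id"] not in si or r["year"] not in yi:
                raise ValueError(f"event in unsurveyed cell/year: "
                                 f"{r['cell_id']}, {r['year']}")
            i, t, j = si[r["cell_id"]], yi[r["year"]], int(r["week"]) - 1
            if effort[i, t, j] <= 0:
                raise ValueError(
                    f"detection in {r['cell_id']} week {j + 1} of {r['year']} "
                    "but no recording effort there: inconsistent inputs")
            det_weeks.add((i, t, j))
            nights_per_cellyear.setdefault((i, t), set()).add(r["night"])

        for (i, t, j) in det_weeks:
            if len(nights_per_cellyear[(i, t)]) >= min_nights:
                Y[i, t, j] = 1.0

    hist = EncounterHistory(Y=Y, effort=effort, site_ids=site_ids, years=list(years))
    hist.validate()
    return hist


def validation_summary(preds: pd.DataFrame, threshold: float = 0.989) -> dict:
    """Manual-validation bookkeeping over predictions at/above threshold."""
    if len(preds):
        _check_confidence(preds)
        sub = preds[preds["confidence"].astype(float) >= threshold]
    else:
        sub = preds
    val = sub["validated"] if "validated" in sub.columns else pd.Series([], dtype=object)
    tp = int((val == "true-positive").sum())
    fp = int((val == "false-positive").sum())
    return {"reviewed": tp + fp, "true_positive": tp, "false_positive": fp,
            "unreviewed": int(len(sub) - tp - fp)}
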