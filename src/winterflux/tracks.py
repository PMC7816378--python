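"""Movement products from raw GPS fixes.

Winter delimitation, hourly resampling, great-circle step lengths, daily
distance series, and the winter-trend polynomial regression with backward
elimination.

Conventions (documented, configurable where noted):

* distances are haversine great-circle with Earth radius 6371.0088 km;
* day boundaries are UTC-6 (wintering-range local time), so a "day"
  matches the biological day;
* hourly resampling keeps the fix nearest each top-of-hour within
  +/- 30 min, ties broken toward the earlier fix;
* "large-scale movement > 50 km" is evaluated on net daily displacement
  (first-to-last fix of the local day), not summed path.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088
LOCAL_UTC_OFFSET = -6  # wintering-range local time
WINTER_END_MONTH_DAY = (2, 28)
WINTER_DAYS = 137


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between lon/lat points (degrees)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, float)) for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def local_day(timestamps: pd.Series) -> pd.Series:
    """Calendar date in UTC-6 local time."""
    ts = pd.to_datetime(timestamps, utc=True)
    return (ts + pd.Timedelta(hours=LOCAL_UTC_OFFSET)).dt.normalize().dt.tz_localize(None)


def _clean(fixes: pd.DataFrame) -> pd.DataFrame:
    fixes = fixes.copy()
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"], utc=True)
    dup = fixes.duplicated(["individual_id", "timestamp"])
    if dup.any():
        log.warning("dropping %d duplicate-timestamp fixes (keeping first)", dup.sum())
        fixes = fixes[~dup]
    return fixes.sort_values(["individual_id", "timestamp"], kind="stable").reset_index(drop=True)


def resample_hourly(fixes: pd.DataFrame) -> pd.DataFrame:
    """At most one fix per hour: the fix nearest each top-of-hour.

    Idempotent: already-hourly data pass through unchanged.
    """
    fixes = _clean(fixes)
    if fixes.empty:
        return fixes
    ts = fixes["timestamp"]
    offset = ts - ts.dt.floor("h")
    # nearest top-of-hour; an exact half-hour tie rounds down so the
    # earlier fix wins when two fixes straddle an hour symmetrically
    nearest = ts.dt.floor("h") + pd.to_timedelta(
        (offset > pd.Timedelta(minutes=30)).astype(int), unit="h"
    )
    dist = (ts - nearest).abs()
    work = fixes.assign(_hour=nearest, _dist=dist)
    # stable sort: among equal distances the earlier fix is kept
    work = work.sort_values(["individual_id", "_hour", "_dist", "timestamp"], kind="stable")
    out = work.groupby(["individual_id", "_hour"], as_index=False, sort=True).first()
    out = out.drop(columns=["_hour", "_dist"])
    return out.sort_values(["individual_id", "timestamp"]).reset_index(drop=True)


def step_lengths(fixes: pd.DataFrame, max_gap_hours: float = 4.0) -> pd.DataFrame:
    """Great-circle step lengths between successive fixes per individual.

    Steps spanning a time gap >= ``max_gap_hours`` are removed: those are
    exactly the missing-fix outliers in an hourly scheme.
    """
    fixes = _clean(fixes)
    out = []
    for ind, grp in fixes.groupby("individual_id", sort=True):
        if len(grp) < 2:
            continue
        lon = grp["lon"].to_numpy()
        lat = grp["lat"].to_numpy()
        ts = grp["timestamp"].to_numpy()
        km = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
        gap = (ts[1:] - ts[:-1]) / np.timedelta64(1, "h")
        keep = gap < max_gap_hours
        out.append(
            pd.DataFrame(
                {
                    "individual_id": ind,
                    "t_start": ts[:-1][keep],
                    "t_end": ts[1:][keep],
                    "km": km[keep],
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=["individual_id", "t_start", "t_end", "km"])
    return pd.concat(out, ignore_index=True)


def delimit_winter(
    fixes: pd.DataFrame,
    winter_end: pd.Timestamp | None = None,
    lat_threshold: float = 40.0,
    move_km: float = 50.0,
    settle_days: int = 4,
) -> pd.DataFrame:
    """Per-individual winter (start, end) instants.

    Start is the first instant the individual is at or below 40 deg N with
    no further > 50 km net-southward daily displacement during the next
    ``settle_days`` days; a qualifying southward hop re-sets the start to
    the day of the hop.  End is the first northward crossing above 40 deg
    N, else 28 February of the winter.  Individuals never below 40 deg N
    are excluded (flagged in the log).
    """
    fixes = _clean(fixes)
    recs = []
    for ind, grp in fixes.groupby("individual_id", sort=True):
        below = grp[grp["lat"] <= lat_threshold]
        if below.empty:
            log.warning("individual %s never at or below %s N; excluded", ind, lat_threshold)
            continue
        start_ts = below["timestamp"].iloc[0]
        grp = grp.assign(_day=local_day(grp["timestamp"]))
        daily = grp.groupby("_day").agg(
            lon_first=("lon", "first"),
            lat_first=("lat", "first"),
            lon_last=("lon", "last"),
            lat_last=("lat", "last"),
            t_first=("timestamp", "first"),
        )
        daily["net_km"] = haversine_km(
            daily["lon_first"], daily["lat_first"], daily["lon_last"], daily["lat_last"]
        )
        daily["southward"] = daily["lat_last"] < daily["lat_first"]
        start_day = local_day(pd.Series([start_ts])).iloc[0]
        hop = daily[
            (daily.index >= start_day)
            & (daily["net_km"] > move_km)
            & daily["southward"]
        ]
        # walk forward: each qualifying hop within settle_days re-sets start
        cur = start_day
        cur_ts = start_ts
        for day, row in hop.iterrows():
            if (day - cur).days <= settle_days:
                cur = day
                cur_ts = row["t_first"]
            elif day > cur:
                break
        start_ts = cur_ts

        if winter_end is None:
            yr = start_ts.year + (1 if start_ts.month >= 7 else 0)
            w_end = pd.Timestamp(yr, *WINTER_END_MONTH_DAY, 23, 59, tz="UTC")
        else:
            w_end = pd.Timestamp(winter_end)
            if w_end.tz is None:
                w_end = w_end.tz_localize("UTC")
        north = grp[(grp["timestamp"] > start_ts) & (grp["lat"] > lat_threshold)]
        end_ts = north["timestamp"].iloc[0] if not north.empty else w_end
        end_ts = min(end_ts, w_end)
        recs.append({"individual_id": ind, "start": start_ts, "end": end_ts})
    return pd.DataFrame(recs, columns=["individual_id", "start", "end"])


def daily_distance(
    steps: pd.DataFrame,
    deployments: pd.DataFrame | None = None,
    origin_day: pd.Timestamp | None = None,
    min_individuals: int = 4,
    n_days: int = WINTER_DAYS,
) -> pd.DataFrame:
    """Cross-individual mean total daily distance, indexed by winter day.

    ``deployments`` (individual_id, start) censors each individual's steps
    before its acclimation-adjusted start.  Day 1 is the earliest
    deployment date (or ``origin_day``); the series ends at day
    ``n_days``.  Days with fewer than ``min_individuals`` contributing
    individuals (the paper's "<= 3" rule) are removed.
    """
    cols = ["winter_day_index", "date", "n_individuals", "mean_km"]
    if steps.empty:
        return pd.DataFrame(columns=cols)
    steps = steps.copy()
    steps["date"] = local_day(steps["t_start"])
    if deployments is not None and len(deployments):
        dep = deployments.set_index("individual_id")["start"]
        dep_day = local_day(dep.reset_index(drop=True))
        dep_day.index = dep.index
        steps = steps[
            steps.apply(
                lambda r: r["date"] >= dep_day.get(r["individual_id"], r["date"]),
                axis=1,
            )
        ]
        origin = dep_day.min() if origin_day is None else pd.Timestamp(origin_day)
    else:
        origin = steps["date"].min() if origin_day is None else pd.Timestamp(origin_day)

    per_ind = steps.groupby(["date", "individual_id"], as_index=False)["km"].sum()
    day = per_ind.groupby("date").agg(
        n_individuals=("individual_id", "nunique"), mean_km=("km", "mean")
    )
    day["winter_day_index"] = (day.index - origin).days + 1
    day = day[(day["winter_day_index"] >= 1) & (day["winter_day_index"] <= n_days)]
    day = day[day["n_individuals"] >= min_individuals]
    day = day.reset_index()
    return day[cols].sort_values("winter_day_index").reset_index(drop=True)


# ---------------------------------------------------------------------------
# winter-trend regression


@dataclass
class TrendResults:
    """Polynomial trend fit of log mean daily distance on winter day index."""

    degree: int
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    rsquared: float
    fvalue: float
    df_model: int
    df_resid: int
    peak_day: int
    shapiro_p: float
    elimination_path: list[tuple[int, float]]
    _ols: object = None

    def predict(self, day_index: np.ndarray) -> np.ndarray:
        d = np.asarray(day_index, float)
        X = np.column_stack([d**k for k in range(self.degree + 1)])
        return X @ self.params.to_numpy()

    def summary(self) -> str:
        lines = [
            "Winter daily-movement trend (OLS on log mean km)",
            f"  retained degree: {self.degree}",
            f"  R^2 = {self.rsquared:.3f}   F({self.df_model}, {self.df_resid}) = {self.fvalue:.2f}",
            f"  peak fitted movement: winter day {self.peak_day}",
            f"  Shapiro-Wilk residual p = {self.shapiro_p:.3f}",
            "  coefficients (term: estimate [SE], p):",
        ]
        for name in self.params.index:
            lines.append(
                f"    {name}: {self.params[name]:.5g} [{self.bse[name]:.3g}], p={self.pvalues[name]:.3g}"
            )
        for deg, p in self.elimination_path:
            lines.append(f"  eliminated degree-{deg} term (p = {p:.3f})")
        return "\n".join(lines)


class DailyTrendModel:
    """Backward-elimination polynomial regression of the daily-distance series.

    The response is the natural log of the cross-individual mean daily
    distance; the predictor is the winter day index with terms up to
    cubic.  Starting from the cubic, the highest-order term is removed
    while its p-value exceeds ``alpha``; elimination stops at the linear
    term.  The Shapiro-Wilk residual-normality p-value is reported, not
    used as a gate.
    """

    def __init__(self, series: pd.DataFrame, max_degree: int = 3):
        series = series.copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            bad = ~np.isfinite(np.log(series["mean_km"].to_numpy(dtype=float)))
        if bad.any():
            warnings.warn(f"dropping {bad.sum()} days with non-positive mean distance")
            series = series[~bad]
        if len(series) < 10:
            raise ValueError("need at least 10 retained days to fit a trend")
        self.series = series.reset_index(drop=True)
        self.max_degree = max_degree

    def fit(self, alpha: float = 0.05) -> TrendResults:
        d = self.series["winter_day_index"].to_numpy(dtype=float)
        y = np.log(self.series["mean_km"].to_numpy(dtype=float))
        degree = self.max_degree
        path: list[tuple[int, float]] = []
        while True:
            if len(y) <= degree + 1:
                raise ValueError("fewer points than regression parameters")
            X = np.column_stack([d**k for k in range(degree + 1)])
            names = ["const"] + [f"day^{k}" for k in range(1, degree + 1)]
            res = sm.OLS(y, pd.DataFrame(X, columns=names)).fit()
            p_high = res.pvalues.iloc[-1]
            if degree > 1 and p_high > alpha:
                path.append((degree, float(p_high)))
                degree -= 1
                continue
            break
        grid = np.arange(d.min(), d.max() + 1)
        Xg = np.column_stack([grid**k for k in range(degree + 1)])
        fitted_grid = Xg @ res.params.to_numpy()
        peak = int(grid[np.argmax(fitted_grid)])
        sw_p = float(stats.shapiro(res.resid)[1]) if len(y) >= 3 else np.nan
        return TrendResults(
            degree=degree,
            params=res.params,
            bse=res.bse,
            pvalues=res.pvalues,
            rsquared=float(res.rsquared),
            fvalue=float(res.fvalue),
            df_model=int(res.df_model),
            df_resid=int(res.df_resid),
            peak_day=peak,
            shapiro_p=sw_p,
            elimination_path=path,
            _ols=res,
        )


def fit_daily_trend(series: pd.DataFrame, alpha: float = 0.05) -> TrendResults:
    """Functional wrapper over :class:`DailyTrendModel`."""
    return DailyTrendModel(series).fit(alpha=alpha)
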