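"""Daily states and weekly capture histories.

Each individual-day gets exactly one state code 1-9: the day's fix
nearest local midnight is point-in-polygon tested against the eight
wintering regions (outside all -> 5 "Other"; no fix -> 9 "not
observed").  Daily series are collapsed into weekly capture histories
with a transition-capturing rule, and summarised into mover percentages
and breeding-region time allocations.

Weekly collapse rule
--------------------
Within a week the observed (non-9) codes are reduced to their run
sequence.  A week with no transition keeps its single state.  Otherwise
the week's code is the destination of the final transition, except that
a terminal return to the week's initial state is ignored unless the week
ends in that state for at least two consecutive observed days.  This is
the minimal rule consistent with all three worked examples:
'BBBBAAA' -> A, 'AAAABBA' -> B, 'AABBCCC' -> C.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .regions import RegionMap
from .tracks import LOCAL_UTC_OFFSET, local_day

log = logging.getLogger(__name__)

NOT_OBSERVED = 9


def assign_daily_state(fixes: pd.DataFrame, regions: RegionMap) -> pd.DataFrame:
    """One state code per individual-day from the fix nearest local midnight.

    Returns columns individual_id, date, state_code.  Days without a fix
    do not appear (they are re-inserted as 9s by ``weekly_collapse``);
    the fix nearest midnight of each local day is used, earlier fix on a
    tie.
    """
    fixes = fixes.copy()
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"], utc=True)
    fixes["date"] = local_day(fixes["timestamp"])
    # distance to the nearer of the local day's two midnights
    midnight0 = (fixes["date"] - pd.Timedelta(hours=LOCAL_UTC_OFFSET)).dt.tz_localize("UTC")
    midnight1 = midnight0 + pd.Timedelta(days=1)
    fixes["_dist"] = pd.concat(
        [(fixes["timestamp"] - midnight0).abs(), (fixes["timestamp"] - midnight1).abs()],
        axis=1,
    ).min(axis=1)
    fixes = fixes.sort_values(
        ["individual_id", "date", "_dist", "timestamp"], kind="stable"
    )
    chosen = fixes.groupby(["individual_id", "date"], as_index=False).first()
    chosen["state_code"] = regions.locate_many(
        chosen["lon"].to_numpy(), chosen["lat"].to_numpy()
    )
    return chosen[["individual_id", "date", "state_code"]]


def collapse_week(codes):
    """Collapse one week of daily state codes to the week's state.

    Codes may be ints 1-9 or arbitrary symbols ('A', 'B', ...); 9 (or
    '9') marks an unobserved day.
    """
    codes = list(codes)
    obs = [c for c in codes if str(c) != str(NOT_OBSERVED)]
    if not obs:
        return type(codes[0])(NOT_OBSERVED) if codes else NOT_OBSERVED
    # run-length collapse to the ordered sequence of distinct visited states
    runs: list[list] = []
    for c in obs:
        if runs and runs[-1][0] == c:
            runs[-1][1] += 1
        else:
            runs.append([c, 1])
    if len(runs) == 1:
        return runs[0][0]
    initial = runs[0][0]
    last_state, last_len = runs[-1]
    if last_state != initial:
        return last_state
    if last_len >= 2:
        return initial
    # terminal one-day return to the initial state: intermediate step only
    return runs[-2][0]


def weekly_collapse(
    daily: pd.DataFrame,
    n_weeks: int | None = None,
    origin_day: pd.Timestamp | None = None,
) -> pd.DataFrame:
    """Collapse daily state series into a weekly capture-history matrix.

    Days are partitioned into consecutive 7-day blocks from winter day 1
    (the earliest date present, or ``origin_day``).  Missing days count
    as 9; weeks that are entirely 9 stay 9.  Returns one row per
    individual with columns week_01..week_NN.
    """
    if daily.empty:
        return pd.DataFrame()
    daily = daily.copy()
    origin = pd.Timestamp(origin_day) if origin_day is not None else daily["date"].min()
    daily["_day_idx"] = (daily["date"] - origin).dt.days
    daily["_week"] = daily["_day_idx"] // 7
    if n_weeks is None:
        n_weeks = int(daily["_week"].max()) + 1
    inds = sorted(daily["individual_id"].unique())
    mat = np.full((len(inds), n_weeks), NOT_OBSERVED, dtype=int)
    for i, ind in enumerate(inds):
        sub = daily[daily["individual_id"] == ind]
        for w, grp in sub.groupby("_week"):
            if 0 <= w < n_weeks:
                week = grp.sort_values("_day_idx")
                mat[i, int(w)] = collapse_week(week["state_code"])
    cols = [f"week_{w + 1:02d}" for w in range(n_weeks)]
    out = pd.DataFrame(mat, columns=cols)
    out.insert(0, "individual_id", inds)
    return out


def history_matrix(histories: pd.DataFrame) -> np.ndarray:
    """Numeric (n_individuals, n_weeks) matrix from a history frame."""
    week_cols = [c for c in histories.columns if c.startswith("week_")]
    return histories[week_cols].to_numpy(dtype=int)


def mover_percentage(n_movers: int, n_total: int) -> float:
    """Percentage of individuals with at least one inter-regional movement."""
    if n_total == 0:
        return 0.0
    return round(100.0 * n_movers / n_total, 1)


def movement_summary(daily: pd.DataFrame) -> dict:
    """Mover counts and regions-used statistics from daily state series.

    A mover is an individual whose located days (codes 1-8) span more
    than one region.  Returns counts, the mover percentage, per-mover
    regions-used mean +/- SE, and per-region individual counts.
    """
    if daily.empty:
        return {
            "n_individuals": 0,
            "n_movers": 0,
            "percent_movers": 0.0,
            "regions_used_mean": np.nan,
            "regions_used_se": np.nan,
            "region_counts": {},
        }
    located = daily[daily["state_code"].between(1, 8)]
    per_ind = located.groupby("individual_id")["state_code"].agg(lambda s: len(set(s)))
    n_total = per_ind.size
    movers = per_ind[per_ind > 1]
    n_movers = int(movers.size)
    region_counts = (
        located.groupby("state_code")["individual_id"].nunique().to_dict()
    )
    mean = float(movers.mean()) if n_movers else np.nan
    se = float(movers.std(ddof=1) / np.sqrt(n_movers)) if n_movers > 1 else np.nan
    return {
        "n_individuals": int(n_total),
        "n_movers": n_movers,
        "percent_movers": mover_percentage(n_movers, n_total),
        "regions_used_mean": mean,
        "regions_used_se": se,
        "region_counts": {int(k): int(v) for k, v in region_counts.items()},
    }


def region_time_allocation(
    daily: pd.DataFrame, group_labels: pd.Series | dict
) -> pd.DataFrame:
    """Per-group proportion of located days spent in each winter region.

    ``group_labels`` maps individual_id to a label (e.g. breeding
    region).  Code-9 days are excluded; each group's row sums to 1.
    Groups with zero located days are omitted with a warning.
    """
    labels = pd.Series(group_labels)
    located = daily[daily["state_code"].between(1, 8)].copy()
    located["group"] = located["individual_id"].map(labels)
    located = located[located["group"].notna()]
    tab = (
        located.groupby(["group", "state_code"]).size().unstack(fill_value=0)
        .reindex(columns=range(1, 9), fill_value=0)
    )
    empty = tab.sum(axis=1) == 0
    if empty.any():
        log.warning("groups with zero located days omitted: %s", list(tab.index[empty]))
        tab = tab[~empty]
    return tab.div(tab.sum(axis=1), axis=0)
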