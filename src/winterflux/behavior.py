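"""Behaviour classification, time budgets, and the budget-ODBA regression.

Bursts are summarised into per-axis static/dynamic features and
classified into four behaviours (foraging, walking, stationary, flight)
with a bootstrap-aggregated decision-tree ensemble (random forest);
accuracy is reported out-of-bag.  Daily per-region time budgets are then
related to regional energy-expenditure contrasts by beta regression with
a logit mean link and constant precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from statsmodels.othermod.betareg import BetaModel

from .energetics import _SAMPLE_COLS, compute_odba
from .simulate import AXES, BEHAVIORS

_AC_LAGS = (1, 2, 3, 4, 5)


def extract_features(bursts: pd.DataFrame) -> pd.DataFrame:
    """Deterministic per-burst feature vectors from calibrated bursts.

    Features: per-axis static mean, dynamic SD and range; burst ODBA; and
    dynamic-component autocorrelations at lags 1-5 (averaged over axes)
    summarising the dominant oscillation.  One row per burst_id.
    """
    rows = []
    meta_cols = [c for c in ("individual_id", "timestamp", "device") if c in bursts.columns]
    for burst_id, grp in bursts.groupby("burst_id", sort=True):
        grp = grp.set_index("axis").loc[list(AXES)]
        arr = grp[_SAMPLE_COLS].to_numpy(dtype=float)
        odba, dyn = compute_odba(arr)
        feat = {"burst_id": burst_id, "odba": odba}
        for a, axis in enumerate(AXES):
            feat[f"static_mean_{axis}"] = arr[a].mean()
            feat[f"dyn_sd_{axis}"] = dyn[a].std(ddof=0)
            feat[f"range_{axis}"] = np.ptp(arr[a])
        for lag in _AC_LAGS:
            acs = []
            for a in range(3):
                d = dyn[a] - dyn[a].mean()
                denom = float(d @ d)
                acs.append(float(d[:-lag] @ d[lag:]) / denom if denom > 0 else 0.0)
            feat[f"dyn_ac_lag{lag}"] = float(np.mean(acs))
        for c in meta_cols:
            feat[c] = grp[c].iloc[0]
        rows.append(feat)
    return pd.DataFrame(rows)


FEATURE_COLUMNS = (
    ["odba"]
    + [f"{stem}_{ax}" for stem in ("static_mean", "dyn_sd", "range") for ax in AXES]
    + [f"dyn_ac_lag{lag}" for lag in _AC_LAGS]
)


@dataclass
class BehaviorClassifier:
    """Random-forest behaviour classifier with out-of-bag accuracy."""

    forest: RandomForestClassifier
    feature_columns: list
    oob_accuracy: float
    confusion: pd.DataFrame

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.forest.predict(features[self.feature_columns].to_numpy(dtype=float))


def train_classifier(
    features: pd.DataFrame,
    labels,
    n_trees: int = 500,
    seed: int = 0,
    min_per_class: int = 50,
) -> BehaviorClassifier:
    """Train the behaviour classifier on labelled burst features.

    Requires >= 2 classes with >= ``min_per_class`` bursts each.  The
    out-of-bag confusion matrix accompanies the OOB accuracy.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 behaviour classes to train")
    if counts.min() < min_per_class:
        raise ValueError(
            f"need >= {min_per_class} bursts per class; got {dict(zip(classes, counts))}"
        )
    cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    X = features[cols].to_numpy(dtype=float)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=True,
        random_state=int(seed) % 2**31,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        forest.fit(X, labels)
    oob_pred = forest.classes_[np.argmax(forest.oob_decision_function_, axis=1)]
    cm = confusion_matrix(labels, oob_pred, labels=forest.classes_)
    return BehaviorClassifier(
        forest=forest,
        feature_columns=cols,
        oob_accuracy=float(forest.oob_score_),
        confusion=pd.DataFrame(cm, index=forest.classes_, columns=forest.classes_),
    )


def time_budget(
    predictions: pd.DataFrame, daily_states: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily behaviour time budgets and regional means.

    ``predictions`` carries individual_id, timestamp (or date),
    behaviour class per burst, and optionally region_code; if absent the
    region is joined from ``daily_states``.  Returns (budgets, regional)
    where budgets has one row per individual-day-region with proportions
    per class summing to 1, and regional has the mean +/- SE per region
    and class over individual-days.
    """
    from .tracks import local_day

    work = predictions.copy()
    if "date" not in work.columns:
        work["date"] = local_day(work["timestamp"])
    if "region_code" not in work.columns:
        if daily_states is None:
            raise ValueError("need region_code or daily_states to resolve regions")
        work = work.merge(daily_states, on=["individual_id", "date"], how="inner")
        work = work.rename(columns={"state_code": "region_code"})
        work = work[work["region_code"] != 9]
    counts = (
        work.groupby(["individual_id", "date", "region_code"])["behavior"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(BEHAVIORS), fill_value=0)
    )
    budgets = counts.div(counts.sum(axis=1), axis=0).reset_index()
    long = budgets.melt(
        id_vars=["individual_id", "date", "region_code"],
        value_vars=list(BEHAVIORS),
        var_name="behavior",
        value_name="proportion",
    )
    regional = (
        long.groupby(["region_code", "behavior"])["proportion"]
        .agg(mean="mean", se=lambda s: s.std(ddof=1) / np.sqrt(len(s)), n="size")
        .reset_index()
    )
    return budgets, regional


# ---------------------------------------------------------------------------
# beta regression of budgets on ODBA contrasts


@dataclass
class BudgetOdbaResults:
    """Beta-regression fit of regional budget proportions on ODBA contrasts."""

    intercept: float
    slope: float
    slope_se: float
    z_statistic: float
    p_value: float
    pseudo_r2: float
    n_regions: int
    loglik: float
    precision: float
    fitted: np.ndarray

    def summary(self) -> str:
        return (
            "Beta regression (logit link, constant precision)\n"
            f"  n regions = {self.n_regions}\n"
            f"  slope = {self.slope:.3f} [{self.slope_se:.3f}],"
            f" Z = {self.z_statistic:.3f}, p = {self.p_value:.3g}\n"
            f"  pseudo-R^2 = {self.pseudo_r2:.2f}"
        )


class BudgetOdbaModel:
    """Relate regional time budgets to regional energy-expenditure contrasts.

    The response is the mean daily proportion of time in a behaviour per
    region (strictly inside (0, 1); boundary values are shrunk with the
    standard (y (n-1) + 0.5) / n correction, with a warning); the
    predictor is the region's back-transformed daily-ODBA difference from
    the reference region.  Maximum-likelihood beta regression with a
    logit mean link and constant precision.
    """

    def __init__(self, proportions, contrasts):
        y = np.asarray(proportions, float)
        x = np.asarray(contrasts, float)
        if y.size != x.size:
            raise ValueError("proportions and contrasts must align")
        if y.size < 4:
            raise ValueError("need at least 4 regions for the beta regression")
        if np.any((y <= 0) | (y >= 1)):
            n = y.size
            warnings.warn(
                "boundary proportions shrunk with (y*(n-1)+0.5)/n before fitting"
            )
            y = (y * (n - 1) + 0.5) / n
        self.y = y
        self.x = x

    def fit(self) -> BudgetOdbaResults:
        X = np.column_stack([np.ones_like(self.x), self.x])
        model = BetaModel(self.y, X)  # default logit mean link, log precision link
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=False)
        params = np.asarray(res.params)
        bse = np.asarray(res.bse)
        eta_fit = X @ params[:2]
        fitted = special.expit(eta_fit)
        eta_obs = special.logit(self.y)
        r = np.corrcoef(eta_fit, eta_obs)[0, 1]
        z = params[1] / bse[1]
        from scipy import stats as sps

        return BudgetOdbaResults(
            intercept=float(params[0]),
            slope=float(params[1]),
            slope_se=float(bse[1]),
            z_statistic=float(z),
            p_value=float(2 * sps.norm.sf(abs(z))),
            pseudo_r2=float(r**2),
            n_regions=int(self.y.size),
            loglik=float(res.llf),
            precision=float(model.link_precision.inverse(params[2])),
            fitted=fitted,
        )


def beta_budget_regression(proportions, contrasts) -> BudgetOdbaResults:
    """Functional wrapper over :class:`BudgetOdbaModel`."""
    return BudgetOdbaModel(proportions, contrasts).fit()
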