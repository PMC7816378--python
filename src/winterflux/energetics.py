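"""ODBA energetics: device harmonisation, dynamic-acceleration decomposition,
and the regional mixed-effects model.

Overall dynamic body acceleration (ODBA) per sample is
``|DAx| + |DAy| + |DAz|`` where the dynamic acceleration of each axis is
the raw signal minus its static (gravity/posture) component, estimated
with a centred 1-s (10-sample) moving average.  A burst's ODBA is the
mean per-sample ODBA, so bursts remain comparable when samples are
missing.

The bounded device family clips at +/- 2048 mV, biasing high-amplitude
behaviours; its calibrated values are harmonised onto the unbounded
family's distribution by quantile mapping with a monotone spline through
matched empirical quantiles, extrapolating linearly beyond the outermost
pair so the clipped mass can map beyond the rail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.interpolate import PchipInterpolator
from scipy import stats

from .simulate import AXES, BURST_SAMPLES, G, MV_PER_MS2

#: built-in affine calibrations (gain, offset) to m/s^2 per device family
DEFAULT_CALIBRATIONS = {
    "bounded": (1.0 / MV_PER_MS2, 0.0),  # mV -> m/s^2
    "unbounded": (G, 0.0),  # G-force -> m/s^2
}

#: the 30 per-axis sample columns of a long-format burst table
SAMPLE_COLUMNS = [f"s{k + 1:02d}" for k in range(BURST_SAMPLES)]
_SAMPLE_COLS = SAMPLE_COLUMNS


def calibrate_units(
    bursts: pd.DataFrame, calibrations: dict[str, tuple[float, float]] | None = None
) -> pd.DataFrame:
    """Convert raw burst samples to m/s^2 with per-device affine maps.

    ``calibrations`` maps device family to (gain, offset):
    value_ms2 = gain * raw + offset.  Raises KeyError naming any device
    without a calibration.
    """
    cal = DEFAULT_CALIBRATIONS if calibrations is None else calibrations
    out = bursts.copy()
    for dev in out["device"].unique():
        if dev not in cal:
            raise KeyError(f"no calibration available for device family '{dev}'")
        gain, offset = cal[dev]
        mask = out["device"] == dev
        out.loc[mask, _SAMPLE_COLS] = out.loc[mask, _SAMPLE_COLS] * gain + offset
    out["units"] = "m/s^2"
    return out


@dataclass
class QuantileMap:
    """Monotone transfer function from a source to a target distribution."""

    source_q: np.ndarray
    target_q: np.ndarray
    _spline: PchipInterpolator
    _target_sorted: np.ndarray = None
    _target_probs: np.ndarray = None

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        lo, hi = self.source_q[0], self.source_q[-1]
        out = self._spline(np.clip(x, lo, hi))
        # linear extrapolation with the end-interval slopes, so values
        # beyond the outermost quantile pair (e.g. clipped mass) map
        # beyond the target's observed range
        slope_lo = self._spline.derivative()(lo)
        slope_hi = self._spline.derivative()(hi)
        out = np.where(x < lo, self.target_q[0] + slope_lo * (x - lo), out)
        out = np.where(x > hi, self.target_q[-1] + slope_hi * (x - hi), out)
        return out

    def transform_sample(self, x) -> np.ndarray:
        """Rank-based distribution matching of a whole sample.

        Unlike the value-wise function, tied values (e.g. the clipped
        mass at a bounded device's rail) are spread across their
        mid-rank probability span of the target quantile function, so a
        censored point mass is restored into the target's tail.  Use
        this to harmonise a full sample; use ``__call__`` to map
        individual values.
        """
        from scipy.stats import rankdata

        x = np.asarray(x, float)
        flat = x.ravel()
        p = (rankdata(flat, method="ordinal") - 0.5) / flat.size
        out = np.interp(p, self._target_probs, self._target_sorted)
        return out.reshape(x.shape)

    def diagnostic_table(self, n: int = 101) -> pd.DataFrame:
        """Matched-quantile table for visual CDF assessment."""
        probs = np.linspace(0, 1, n)
        src = np.quantile(self.source_q, probs)
        return pd.DataFrame(
            {"prob": probs, "source": src, "mapped": self(src),
             "target": np.quantile(self.target_q, probs)}
        )


def quantile_map(
    source: np.ndarray, target: np.ndarray, n_quantiles: int = 1000,
    min_samples: int = 1000,
) -> QuantileMap:
    """Fit the bounded-to-unbounded quantile-mapping transfer function.

    A monotone piecewise-cubic (PCHIP) spline is fitted through matched
    empirical quantile pairs of the two samples; monotonicity of the
    transfer is guaranteed by construction.
    """
    source = np.asarray(source, float).ravel()
    target = np.asarray(target, float).ravel()
    if source.size < min_samples or target.size < min_samples:
        raise ValueError(f"need at least {min_samples} values in source and target")
    if np.ptp(source) == 0 or np.ptp(target) == 0:
        raise ValueError("degenerate (constant) source or target sample")
    probs = np.linspace(0.0, 1.0, n_quantiles)
    qs = np.quantile(source, probs)
    qt = np.quantile(target, probs)
    # collapse ties in the source grid (e.g. the clipped rail) keeping a
    # strictly increasing knot sequence
    keep = np.concatenate([[True], np.diff(qs) > 0])
    qs, qt = qs[keep], qt[keep]
    qt = np.maximum.accumulate(qt)  # guard tiny non-monotone wiggles
    spline = PchipInterpolator(qs, qt)
    tgt_sorted = np.sort(target)
    tgt_probs = (np.arange(target.size) + 0.5) / target.size
    return QuantileMap(
        source_q=qs,
        target_q=qt,
        _spline=spline,
        _target_sorted=tgt_sorted,
        _target_probs=tgt_probs,
    )


# ---------------------------------------------------------------------------
# ODBA


def _moving_average(x: np.ndarray, window: int, edge: str) -> np.ndarray:
    if edge == "truncate":
        s = pd.Series(x)
        return s.rolling(window, center=True, min_periods=1).mean().to_numpy()
    if edge == "discard":
        out = pd.Series(x).rolling(window, center=True).mean().to_numpy()
        return out
    raise ValueError(f"unknown edge mode '{edge}'")


def compute_odba(
    samples: np.ndarray, window: int = 10, edge: str = "truncate"
) -> tuple[float, np.ndarray]:
    """ODBA of one calibrated burst.

    ``samples`` is (3, 30) in m/s^2.  Static acceleration per axis is a
    centred ``window``-sample moving average (1 s at 10 Hz); dynamic
    acceleration is raw minus static; per-sample ODBA sums the absolute
    dynamic components; the burst value is the mean over samples.
    Returns (burst_odba, dynamic (3, 30) array).  Edge windows are
    truncated by default; ``edge='discard'`` drops edge samples instead.
    """
    samples = np.asarray(samples, float)
    if samples.shape != (3, BURST_SAMPLES):
        raise ValueError(f"expected (3, {BURST_SAMPLES}) samples, got {samples.shape}")
    dyn = np.empty_like(samples)
    for a in range(3):
        dyn[a] = samples[a] - _moving_average(samples[a], window, edge)
    per_sample = np.abs(dyn).sum(axis=0)
    odba = float(np.nanmean(per_sample))
    return odba, dyn


def burst_odba_table(
    bursts: pd.DataFrame,
    window: int = 10,
    edge: str = "truncate",
    harmonize: QuantileMap | None = None,
) -> pd.DataFrame:
    """Per-burst ODBA from a long-format calibrated burst table.

    One output row per burst: burst_id, individual_id, timestamp, device,
    odba.  If ``harmonize`` is given, bounded-family samples pass through
    the quantile-mapping transfer first.
    """
    work = bursts.copy()
    if harmonize is not None:
        mask = work["device"] == "bounded"
        work.loc[mask, _SAMPLE_COLS] = harmonize(
            work.loc[mask, _SAMPLE_COLS].to_numpy()
        )
    rows = []
    meta_cols = [c for c in ("individual_id", "timestamp", "device") if c in work.columns]
    for burst_id, grp in work.groupby("burst_id", sort=True):
        grp = grp.set_index("axis").loc[list(AXES)]
        arr = grp[_SAMPLE_COLS].to_numpy(dtype=float)
        odba, _ = compute_odba(arr, window=window, edge=edge)
        rec = {"burst_id": burst_id, "odba": odba}
        for c in meta_cols:
            rec[c] = grp[c].iloc[0]
        rows.append(rec)
    return pd.DataFrame(rows)


def daily_odba(odba_bursts: pd.DataFrame, daily_states: pd.DataFrame) -> pd.DataFrame:
    """Mean ODBA per individual per region per day.

    ``daily_states`` carries (individual_id, date, state_code); bursts
    are matched on the local day.  Days whose state is 9 (no region) are
    dropped.  Returns individual_id, date, region_code, daily_odba,
    n_bursts.
    """
    from .tracks import local_day

    work = odba_bursts.copy()
    work["date"] = local_day(work["timestamp"])
    merged = work.merge(daily_states, on=["individual_id", "date"], how="inner")
    merged = merged[merged["state_code"] != 9]
    out = (
        merged.groupby(["individual_id", "date", "state_code"], as_index=False)
        .agg(daily_odba=("odba", "mean"), n_bursts=("odba", "size"))
        .rename(columns={"state_code": "region_code"})
    )
    return out


# ---------------------------------------------------------------------------
# regional mixed model


def ihs(x):
    """Inverse hyperbolic sine, ln(x + sqrt(x^2 + 1))."""
    return np.arcsinh(x)


@dataclass
class RegionEffectResults:
    """Mixed-model fit of transformed daily ODBA on wintering region."""

    fe_params: pd.Series
    fe_bse: pd.Series
    fe_pvalues: pd.Series
    reference: str
    var_individual: float
    var_winter: float
    var_resid: float
    marginal_r2: float
    conditional_r2: float
    pairwise: pd.DataFrame
    transform_mean: float
    transform_sd: float
    transform_order: str
    region_levels: list
    f_statistic: float
    f_df: tuple

    def region_effect(self, region) -> float:
        """Fixed-effect coefficient of a region versus the reference (0 there)."""
        if str(region) == str(self.reference):
            return 0.0
        for name in self.fe_params.index:
            if f"[T.{region}]" in name:
                return float(self.fe_params[name])
        raise KeyError(region)

    def back_transformed_contrasts(self) -> pd.Series:
        """Difference in back-transformed expected daily ODBA vs the reference.

        Inverts the full response transform chain (IHS then the global
        standardisation) at the fitted region means.
        """
        inv = lambda y: self.transform_mean + self.transform_sd * np.sinh(y)
        if self.transform_order == "ihs_then_standardize":
            inv = lambda y: np.sinh(self.transform_mean + self.transform_sd * y)
        mu0 = float(self.fe_params.get("Intercept", 0.0))
        out = {}
        for reg in self.region_levels:
            out[reg] = inv(mu0 + self.region_effect(reg)) - inv(mu0)
        return pd.Series(out)

    def summary(self) -> str:
        lines = [
            "Regional daily-ODBA mixed model (crossed random intercepts:"
            " individual, winter)",
            f"  reference region: {self.reference}",
            f"  marginal R^2 = {self.marginal_r2:.3f}, conditional R^2 = {self.conditional_r2:.3f}",
            f"  F({self.f_df[0]}, {self.f_df[1]}) = {self.f_statistic:.2f} (fixed effects)",
            "  fixed effects (vs reference):",
        ]
        for name in self.fe_params.index:
            lines.append(
                f"    {name}: {self.fe_params[name]:+.3f}"
                f" [{self.fe_bse[name]:.3f}], p={self.fe_pvalues[name]:.3g}"
            )
        lines.append(
            f"  random-effect variances: individual {self.var_individual:.4f},"
            f" winter {self.var_winter:.4f}, residual {self.var_resid:.4f}"
        )
        sig = self.pairwise[self.pairwise["p_adj"] <= 0.05]
        lines.append(
            f"  pairwise contrasts: {len(sig)}/{len(self.pairwise)} significant"
            " after single-step max-|t| adjustment"
        )
        return "\n".join(lines)


class RegionOdbaModel:
    """Linear mixed model of daily ODBA on wintering region.

    The response is centred and standardised, then inverse-hyperbolic-
    sine transformed (order switchable), with region as the fixed effect
    (reference region '2' = MAV) and individual and winter as crossed
    random intercepts fitted by REML.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        reference="2",
        transform_order: str = "standardize_then_ihs",
    ):
        records = records.copy()
        if records["region_code"].nunique() < 2:
            raise ValueError("need at least 2 regions to model a region effect")
        if records["individual_id"].nunique() < 2:
            raise ValueError("need at least 2 individuals")
        if "winter" not in records.columns:
            records["winter"] = "winter-1"
        records["region"] = records["region_code"].astype(str)
        self.reference = str(reference)
        if self.reference not in set(records["region"]):
            self.reference = sorted(set(records["region"]))[0]
        x = records["daily_odba"].to_numpy(dtype=float)
        self.transform_mean = float(x.mean())
        self.transform_sd = float(x.std(ddof=0)) or 1.0
        if transform_order == "standardize_then_ihs":
            records["y"] = ihs((x - self.transform_mean) / self.transform_sd)
        elif transform_order == "ihs_then_standardize":
            z = ihs(x)
            self.transform_mean = float(z.mean())
            self.transform_sd = float(z.std(ddof=0)) or 1.0
            records["y"] = (z - self.transform_mean) / self.transform_sd
        else:
            raise ValueError(f"unknown transform_order '{transform_order}'")
        self.transform_order = transform_order
        self.records = records

    def fit(self, adjust_draws: int = 100_000, seed: int = 0) -> RegionEffectResults:
        data = self.records
        two_winters = data["winter"].nunique() > 1
        vc = {"individual": "0 + C(individual_id)"}
        if two_winters:
            vc["winter"] = "0 + C(winter)"
        formula = f"y ~ C(region, Treatment('{self.reference}'))"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                formula,
                data,
                groups=np.ones(len(data)),
                re_formula="0",
                vc_formula=vc,
            )
            try:
                res = model.fit(reml=True)
            except Exception:
                warnings.warn(
                    "crossed random-effects fit failed; falling back to an "
                    "individual-only random intercept"
                )
                model = smf.mixedlm(
                    formula,
                    data,
                    groups=data["individual_id"],
                    re_formula="1",
                )
                res = model.fit(reml=True)
                two_winters = False

        fe = res.fe_params
        k = len(fe)
        var_ind = float(res.vcomp[0]) if len(res.vcomp) else float(
            np.asarray(res.cov_re).ravel()[0]
        )
        var_win = float(res.vcomp[1]) if (two_winters and len(res.vcomp) > 1) else 0.0
        var_resid = float(res.scale)
        X = model.exog
        fitted_fixed = X @ fe.to_numpy()
        var_fixed = float(np.var(fitted_fixed, ddof=0))
        denom = var_fixed + var_ind + var_win + var_resid
        marginal_r2 = var_fixed / denom
        conditional_r2 = (var_fixed + var_ind + var_win) / denom

        # joint F-type statistic for the region effect (Wald)
        region_idx = [i for i, n in enumerate(fe.index) if n != "Intercept"]
        cov_fe = np.asarray(res.cov_params())[:k, :k]
        beta_r = fe.to_numpy()[region_idx]
        cov_r = cov_fe[np.ix_(region_idx, region_idx)]
        wald = float(beta_r @ np.linalg.solve(cov_r, beta_r))
        df1 = len(region_idx)
        df2 = len(data) - k
        f_stat = wald / df1

        pairwise = self._pairwise(fe, cov_fe, adjust_draws, seed)
        return RegionEffectResults(
            fe_params=fe,
            fe_bse=res.bse_fe,
            fe_pvalues=res.pvalues[: len(fe)],
            reference=self.reference,
            var_individual=var_ind,
            var_winter=var_win,
            var_resid=var_resid,
            marginal_r2=marginal_r2,
            conditional_r2=conditional_r2,
            pairwise=pairwise,
            transform_mean=self.transform_mean,
            transform_sd=self.transform_sd,
            transform_order=self.transform_order,
            region_levels=sorted(set(self.records["region"])),
            f_statistic=f_stat,
            f_df=(df1, df2),
        )

    def _pairwise(self, fe, cov_fe, n_draws: int, seed: int) -> pd.DataFrame:
        """All region-pair contrasts with single-step max-|t| adjustment.

        Adjusted p-values come from the joint normal distribution of all
        contrast statistics (Monte Carlo on the max-|z| null).
        """
        levels = sorted(set(self.records["region"]))
        names = list(fe.index)

        def coef_vector(region):
            v = np.zeros(len(names))
            for i, n in enumerate(names):
                if f"[T.{region}]" in n:
                    v[i] = 1.0
            return v

        contrasts = []
        labels = []
        for i, a in enumerate(levels):
            for b in levels[i + 1:]:
                contrasts.append(coef_vector(a) - coef_vector(b))
                labels.append(f"{a} - {b}")
        C = np.array(contrasts)
        est = C @ fe.to_numpy()
        cov = C @ cov_fe @ C.T
        se = np.sqrt(np.diag(cov))
        z = est / se
        corr = cov / np.outer(se, se)
        # symmetrise and regularise for sampling
        corr = (corr + corr.T) / 2 + 1e-10 * np.eye(len(se))
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(corr)
        draws = rng.standard_normal((n_draws, len(se))) @ L.T
        maxabs = np.abs(draws).max(axis=1)
        p_adj = np.array([(maxabs >= abs(zk)).mean() for zk in z])
        p_raw = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"contrast": labels, "estimate": est, "se": se, "z": z,
             "p_raw": p_raw, "p_adj": p_adj}
        )


def fit_region_model(records: pd.DataFrame, **kwargs) -> RegionEffectResults:
    """Functional wrapper over :class:`RegionOdbaModel`."""
    fit_kwargs = {k: kwargs.pop(k) for k in ("adjust_draws", "seed") if k in kwargs}
    return RegionOdbaModel(records, **kwargs).fit(**fit_kwargs)
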