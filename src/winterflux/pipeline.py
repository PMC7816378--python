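"""Pipeline orchestration: simulate -> tracks -> history -> fit-multistate
-> odba -> behaviour -> report, as one reproducible run.

All randomness derives from a single root seed; each stage gets a
deterministic sub-seed.  Every stage writes its products into the run
directory and never mutates another stage's outputs; a manifest records
versions, seeds, and input digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulate import SimConfig

log = logging.getLogger("winterflux.pipeline")

STAGES = ("simulate", "tracks", "history", "fit-multistate", "odba", "behavior", "report")


@dataclass
class RunConfig:
    """Full configuration of a pipeline run (serialised into the run dir)."""

    seed: int = 42
    out_dir: str = "winterflux_run"
    stages: tuple = STAGES
    # simulation
    n_individuals: int = 40
    n_weeks: int = 19
    gap_rate: float = 0.1
    device_mix: float = 0.5
    bursts_per_day: int = 48
    # analysis
    alpha: float = 0.05
    mcmc_chains: int = 3
    mcmc_iterations: int = 4000
    mcmc_burn_in: int = 1000
    mcmc_thin: int = 5
    harmonize: bool = True
    n_trees: int = 300
    train_bursts_per_class: int = 500

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        for key, val in raw.items():
            if isinstance(val, dict):  # sections of flat key-values
                flat.update(val)
            else:
                flat[key] = val
        known = {f for f in cls.__dataclass_fields__}
        cfg = cls(**{k: v for k, v in flat.items() if k in known})
        if "stages" in flat:
            cfg.stages = tuple(flat["stages"])
        return cfg

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % 2**31


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in dependency order; returns the run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "winterflux": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "stages_run": [],
        "digests": {},
    }
    enabled = set(config.stages)

    def done(stage, *paths):
        manifest["stages_run"].append(stage)
        for p in paths:
            manifest["digests"][p.name] = _digest(p)
        log.info("stage %s complete", stage)

    def require(path: Path, producer: str):
        if not path.exists():
            raise FileNotFoundError(
                f"missing upstream artifact {path.name}: run the '{producer}' stage first"
            )
        return path

    # ------------------------------------------------------------------ simulate
    if "simulate" in enabled:
        from .regions import RegionMap, simulate_regions
        from .simulate import (
            behavior_schedule,
            simulate_bursts,
            simulate_capture_histories,
            simulate_tracks,
            truth_to_json,
        )

        seed = config.stage_seed("simulate")
        sim = SimConfig(
            n_individuals=config.n_individuals,
            n_weeks=config.n_weeks,
            gap_rate=config.gap_rate,
            device_mix=config.device_mix,
            seed=seed,
        )
        regions = simulate_regions(seed)
        regions.save(out / "regions.geojson")
        y, truth = simulate_capture_histories(sim)
        np.savetxt(out / "true_states.csv", truth.latent_states, fmt="%d", delimiter=",")
        fixes = simulate_tracks(sim, truth, regions)
        fixes.to_csv(out / "fixes.csv", index=False)
        sched = behavior_schedule(sim, truth, bursts_per_day=config.bursts_per_day)
        bursts = simulate_bursts(sim, sched)
        bursts.to_csv(out / "bursts.csv", index=False)
        sched.drop(columns=["region_code"]).to_csv(out / "burst_schedule.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(truth_to_json(sim), fh, indent=1)
        done("simulate", out / "fixes.csv", out / "bursts.csv", out / "regions.geojson")

    # ------------------------------------------------------------------ tracks
    if "tracks" in enabled:
        from .tracks import DailyTrendModel, daily_distance, delimit_winter, resample_hourly, step_lengths

        fixes = pd.read_csv(require(out / "fixes.csv", "simulate"), parse_dates=["timestamp"])
        winters = delimit_winter(fixes)
        winters.to_csv(out / "winter_limits.csv", index=False)
        hourly = resample_hourly(fixes)
        steps = step_lengths(hourly)
        series = daily_distance(steps, deployments=winters.rename(columns={"start": "start"}))
        series.to_csv(out / "daily_distance.csv", index=False)
        trend = None
        if len(series) >= 10:
            trend = DailyTrendModel(series).fit(alpha=config.alpha)
            with open(out / "trend_fit.json", "w") as fh:
                json.dump(
                    {
                        "degree": trend.degree,
                        "coefficients": trend.params.to_dict(),
                        "r_squared": trend.rsquared,
                        "f_statistic": trend.fvalue,
                        "df": [trend.df_model, trend.df_resid],
                        "peak_day": trend.peak_day,
                        "shapiro_p": trend.shapiro_p,
                    },
                    fh,
                    indent=1,
                )
        done("tracks", out / "daily_distance.csv")

    # ------------------------------------------------------------------ history
    if "history" in enabled:
        from .regions import RegionMap
        from .history import assign_daily_state, movement_summary, weekly_collapse

        fixes = pd.read_csv(require(out / "fixes.csv", "simulate"), parse_dates=["timestamp"])
        regions = RegionMap.load(require(out / "regions.geojson", "simulate"))
        daily = assign_daily_state(fixes, regions)
        daily.to_csv(out / "daily_states.csv", index=False)
        histories = weekly_collapse(daily, n_weeks=config.n_weeks)
        histories.to_csv(out / "capture_histories.csv", index=False)
        with open(out / "movement_summary.json", "w") as fh:
            json.dump(movement_summary(daily), fh, indent=1, default=float)
        done("history", out / "capture_histories.csv")

    # ------------------------------------------------------------------ multistate
    if "fit-multistate" in enabled:
        from .multistate import MultistateModel

        histories = pd.read_csv(require(out / "capture_histories.csv", "history"))
        model = MultistateModel(histories)
        res = model.fit(
            chains=config.mcmc_chains,
            iterations=config.mcmc_iterations,
            burn_in=config.mcmc_burn_in,
            thin=config.mcmc_thin,
            seed=config.stage_seed("fit-multistate"),
        )
        res.summary_frame().to_csv(out / "posterior_summary.csv", index=False)
        flat = res.psi_flat
        pd.DataFrame(
            flat.reshape(flat.shape[0], -1),
            columns=[f"psi_{r + 1}_{s + 1}" for r in range(8) for s in range(8)],
        ).to_csv(out / "psi_draws.csv", index=False, float_format="%.5f")
        with open(out / "multistate_summary.txt", "w") as fh:
            fh.write(res.summary() + "\n")
        done("fit-multistate", out / "posterior_summary.csv")

    # ------------------------------------------------------------------ odba
    if "odba" in enabled:
        from .energetics import (
            RegionOdbaModel,
            burst_odba_table,
            calibrate_units,
            daily_odba,
            quantile_map,
        )

        bursts = pd.read_csv(require(out / "bursts.csv", "simulate"), parse_dates=["timestamp"])
        daily_states = pd.read_csv(
            require(out / "daily_states.csv", "history"), parse_dates=["date"]
        )
        cal = calibrate_units(bursts)
        qm = None
        if config.harmonize:
            from .energetics import _SAMPLE_COLS

            src = cal.loc[cal["device"] == "bounded", _SAMPLE_COLS].to_numpy().ravel()
            tgt = cal.loc[cal["device"] == "unbounded", _SAMPLE_COLS].to_numpy().ravel()
            if src.size >= 1000 and tgt.size >= 1000:
                qm = quantile_map(src, tgt)
        per_burst = burst_odba_table(cal, harmonize=qm)
        per_burst.to_csv(out / "burst_odba.csv", index=False)
        records = daily_odba(per_burst, daily_states)
        records.to_csv(out / "daily_odba.csv", index=False)
        if records["region_code"].nunique() >= 2:
            fit = RegionOdbaModel(records).fit(seed=config.stage_seed("odba"))
            with open(out / "odba_model.json", "w") as fh:
                json.dump(
                    {
                        "reference": fit.reference,
                        "coefficients": fit.fe_params.to_dict(),
                        "marginal_r2": fit.marginal_r2,
                        "conditional_r2": fit.conditional_r2,
                        "back_transformed_contrasts": fit.back_transformed_contrasts().to_dict(),
                        "pairwise": fit.pairwise.to_dict(orient="records"),
                    },
                    fh,
                    indent=1,
                )
        done("odba", out / "daily_odba.csv")

    # ------------------------------------------------------------------ behavior
    if "behavior" in enabled:
        from .behavior import (
            beta_budget_regression,
            extract_features,
            time_budget,
            train_classifier,
        )
        from .simulate import BEHAVIORS, behavior_schedule, simulate_bursts

        seed = config.stage_seed("behavior")
        bursts = pd.read_csv(require(out / "bursts.csv", "simulate"), parse_dates=["timestamp"])
        sched = pd.read_csv(
            require(out / "burst_schedule.csv", "simulate"), parse_dates=["timestamp"]
        )
        daily_states = pd.read_csv(
            require(out / "daily_states.csv", "history"), parse_dates=["date"]
        )
        from .energetics import calibrate_units

        cal = calibrate_units(bursts)
        feats = extract_features(cal)

        # labelled training set from the generator's known classes
        rng = np.random.default_rng(seed)
        n_per = config.train_bursts_per_class
        train_sched = pd.DataFrame(
            {
                "individual_id": "TRAIN",
                "timestamp": pd.Timestamp("2016-01-01", tz="UTC"),
                "behavior": np.repeat(list(BEHAVIORS), n_per),
                "device": "unbounded",
            }
        )
        sim = SimConfig(seed=seed)
        train_bursts = calibrate_units(simulate_bursts(sim, train_sched, rng=rng))
        train_feats = extract_features(train_bursts)
        clf = train_classifier(train_feats, train_sched["behavior"], n_trees=config.n_trees, seed=seed)

        preds = sched.copy()
        preds["behavior"] = clf.predict(feats)
        budgets, regional = time_budget(preds, daily_states)
        budgets.to_csv(out / "time_budgets.csv", index=False)
        regional.to_csv(out / "regional_budgets.csv", index=False)

        result = {"oob_accuracy": clf.oob_accuracy}
        odba_json = out / "odba_model.json"
        if odba_json.exists():
            with open(odba_json) as fh:
                odba_fit = json.load(fh)
            contrasts = pd.Series(odba_fit["back_transformed_contrasts"])
            forage = regional[regional["behavior"] == "foraging"].set_index("region_code")["mean"]
            common = [r for r in contrasts.index if int(float(r)) in forage.index or str(r) in forage.index.astype(str)]
            forage.index = forage.index.astype(str)
            common = [r for r in contrasts.index if str(r) in forage.index]
            if len(common) >= 4:
                fit = beta_budget_regression(
                    forage.loc[[str(c) for c in common]].to_numpy(),
                    contrasts.loc[common].to_numpy(),
                )
                result["foraging_beta_regression"] = {
                    "slope": fit.slope,
                    "z": fit.z_statistic,
                    "pseudo_r2": fit.pseudo_r2,
                }
        with open(out / "behavior_fit.json", "w") as fh:
            json.dump(result, fh, indent=1)
        done("behavior", out / "time_budgets.csv")

    # ------------------------------------------------------------------ report
    if "report" in enabled:
        lines = ["winterflux run report", "=" * 40]
        ms = out / "movement_summary.json"
        if ms.exists():
            with open(ms) as fh:
                s = json.load(fh)
            lines += [
                "",
                f"Movers: {s['n_movers']} of {s['n_individuals']} ({s['percent_movers']}%)",
                f"Regions used per mover: {s['regions_used_mean']:.2f}"
                + (f" +/- {s['regions_used_se']:.2f} SE" if s["regions_used_se"] == s["regions_used_se"] else ""),
            ]
        pst = out / "multistate_summary.txt"
        if pst.exists():
            lines += ["", pst.read_text().rstrip()]
        om = out / "odba_model.json"
        if om.exists():
            with open(om) as fh:
                o = json.load(fh)
            lines += [
                "",
                "Daily-ODBA regional model:",
                f"  marginal R^2 = {o['marginal_r2']:.3f}, conditional R^2 = {o['conditional_r2']:.3f}",
            ]
        bf = out / "behavior_fit.json"
        if bf.exists():
            with open(bf) as fh:
                b = json.load(fh)
            lines += ["", f"Behavior classifier OOB accuracy: {b['oob_accuracy'] * 100:.1f}%"]
            if "foraging_beta_regression" in b:
                r = b["foraging_beta_regression"]
                lines.append(
                    f"Foraging-vs-ODBA beta regression: slope {r['slope']:.2f},"
                    f" Z = {r['z']:.2f}, pseudo-R^2 = {r['pseudo_r2']:.2f}"
                )
        (out / "report.txt").write_text("\n".join(lines) + "\n")
        done("report", out / "report.txt")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
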